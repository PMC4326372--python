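"""Generate the reference synthetic dataset for the downstream analyses.

Draws one default-size matrix (20,000 probes, canonical 20-array design,
5 planted modules of 50 genes, 30 planted 8-fold seeds per comparison) with
rng_seed=1. The bulky matrix/design TSVs go under scratch/data/ (regenerable
intermediates); the ground-truth labels, which later steps score against,
go under results/.
"""

from pathlib import Path

from cosreg import SimulationConfig, simulate
from cosreg.io_formats import write_expression_tsv, write_table

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(rng_seed=1)
    matrix, truth = simulate(config)
    write_expression_tsv(matrix, DATA / "matrix.tsv", DATA / "design.tsv")
    write_table(truth.to_frame(), RESULTS / "ground_truth.tsv", kind="truth")
    n_members = sum(len(m) for m in truth.module_members.values())
    n_seeds = sum(len(s) for s in truth.planted_seeds.values())
    print(
        f"simulated {matrix.n_probes} probes x {matrix.n_samples} samples; "
        f"{len(truth.module_members)} modules ({n_members} member probes), "
        f"{n_seeds} planted seeds -> {DATA}"
    )


if __name__ == "__main__":
    main()
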