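"""Generate the study-shaped synthetic cohort used by the later steps.

Writes the count table, metadata, and ground truth under results/cohort/.
The cohort mirrors the study layout (24 paired + 3 early-only + 1 late-only
controls; 9 paired + 2 early-only cases) with a 2x sequencing-depth
confound on the case group and five implanted 8-fold effects.
"""
from pathlib import Path

from consenda import io_profiles as iop
from consenda import synthetic_data as sd

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 20240901


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = sd.SimConfig(n_features=300, n_diff=5, depth_group_shift=2.0, seed=SEED)
    table, meta, truth = sd.simulate_cohort(cfg, roster=sd.study_roster())
    iop.write_table(table, OUT / "counts.tsv")
    iop.write_metadata(meta, OUT / "metadata.tsv")
    truth.to_json(OUT / "truth.json")
    n_ctrl = (meta.data["group"] == "control").sum()
    n_case = (meta.data["group"] == "case").sum()
    print(f"cohort: {table.n_samples} samples ({n_ctrl} control / {n_case} case), "
          f"{table.n_features} features")
    print(f"implanted features: {sorted(truth.diff_features)}")
    print(f"wrote {OUT}/counts.tsv, metadata.tsv, truth.json")


if __name__ == "__main__":
    main()
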