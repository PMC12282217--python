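"""Sequencing-depth confound controls.

Tests library size by group, then repeats the late-time-point consensus
analysis on a depth-matched control subset (min-threshold rule) to see
which calls survive when the depth difference is removed.
"""
import json
from pathlib import Path

from consenda import consensus as cns
from consenda import da_engines as eng
from consenda import evaluation as ev
from consenda import io_profiles as iop

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 20240905


def main():
    out = BASE / "depth_controls"
    out.mkdir(parents=True, exist_ok=True)
    table = iop.read_table(BASE / "cohort" / "counts.tsv", unit="count", level="sgb")
    meta = iop.read_metadata(BASE / "cohort" / "metadata.tsv")
    late = [s for s in table.sample_ids if meta.data.loc[s, "timepoint"] == "late"]
    table = table.select_samples(late)
    late_meta = iop.SampleMetadata(meta.data.loc[late])

    depth = ev.depth_group_test(late_meta)
    print(f"library size by group: rank-sum p = {depth['p']:.3g}, "
          f"medians {depth['medians']}")

    keep = ev.depth_matched_subset(late_meta, mode="min_threshold")
    n_ctrl = sum(late_meta.data.loc[keep, "group"] == "control")
    n_case = len(keep) - n_ctrl
    print(f"depth-matched subset: {n_ctrl} controls + {n_case} cases retained")

    cfg = eng.EngineConfig(mc_samples=256, n_perm=499, seed=SEED)
    results = {}
    for label, tab, md in (("full", table, meta),
                           ("matched", table.select_samples(keep), meta)):
        run = eng.run_all_engines({"sgb": tab}, md, eng.Design(),
                                  input_mode="proportions", cfg=cfg)
        cons = cns.consensus_across_levels(run["results"])
        main_tier, _ = cns.split_tiers(cons)
        results[label] = sorted(main_tier["feature_id"])
        print(f"{label} cohort: {len(main_tier)} consensus features")
    with open(out / "summary.json", "w") as fh:
        json.dump({"depth_test": depth, "subset": {"controls": int(n_ctrl),
                                                   "cases": int(n_case)},
                   "consensus": results}, fh, indent=2)


if __name__ == "__main__":
    main()
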