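"""Majority-vote consensus per input mode and the method-1 vs method-2
overlap, stratified by vote count. Reads the per-engine tables from step 03
and writes consensus tables under results/consensus/.
"""
import json
from pathlib import Path

import pandas as pd

from consenda import consensus as cns

BASE = Path(__file__).resolve().parent.parent / "results"


def load_results(tag: str) -> dict:
    out = {}
    for path in sorted((BASE / "da").glob(f"{tag}_*_*.tsv")):
        _, level, engine = path.stem.split("_", 2)
        out[(level, engine)] = pd.read_csv(path, sep="\t")
    return out


def main():
    out = BASE / "consensus"
    out.mkdir(parents=True, exist_ok=True)
    consensus = {}
    for tag in ("method1", "method2"):
        cons = cns.consensus_across_levels(load_results(tag))
        main_tier, supp_tier = cns.split_tiers(cons)
        cons.to_csv(out / f"{tag}_full.tsv", sep="\t", index=False)
        main_tier.to_csv(out / f"{tag}_main.tsv", sep="\t", index=False)
        supp_tier.to_csv(out / f"{tag}_supplementary.tsv", sep="\t", index=False)
        consensus[tag] = cons
        print(f"{tag}: {len(main_tier)} consensus features, "
              f"{len(supp_tier)} supplementary-tier (1-2 votes)")
        for _, row in main_tier.iterrows():
            print(f"  {row['feature_id']} votes={row['n_significant']} "
                  f"direction={row['majority_direction']:+d}")
    cmp = cns.compare_methods(consensus["method1"], consensus["method2"])
    print(f"shared consensus calls: {len(cmp['shared'])}; "
          f"method-1 only: {len(cmp['only_m1'])}; method-2 only: {len(cmp['only_m2'])}")
    with open(out / "method_comparison.json", "w") as fh:
        json.dump({"shared": [list(x) for x in cmp["shared"]],
                   "only_m1": [list(x) for x in cmp["only_m1"]],
                   "only_m2": [list(x) for x in cmp["only_m2"]],
                   "by_votes": {str(k): v for k, v in cmp["by_votes"].items()}},
                  fh, indent=2)


if __name__ == "__main__":
    main()
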