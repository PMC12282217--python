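"""Tool-concordance metrics and ground-truth benchmarking.

For each input mode, scores every engine against the consensus set
(precision/recall proxies and normalised call counts) and against the
implanted ground truth. Writes results/benchmark/.
"""
import json
from pathlib import Path

import pandas as pd

from consenda import consensus as cns
from consenda import evaluation as ev
from consenda.synthetic_data import SimTruth

BASE = Path(__file__).resolve().parent.parent / "results"


def main():
    out = BASE / "benchmark"
    out.mkdir(parents=True, exist_ok=True)
    truth = SimTruth.from_json(BASE / "cohort" / "truth.json")
    records = []
    for tag in ("method1", "method2"):
        per_engine = {}
        for path in sorted((BASE / "da").glob(f"{tag}_*_*.tsv")):
            _, _, engine = path.stem.split("_", 2)
            per_engine[engine] = pd.read_csv(path, sep="\t")
        cons = cns.vote(per_engine, level="sgb")
        records.append(ev.tool_metrics(per_engine, cons, dataset_id=tag))
        bench = {e: ev.benchmark_vs_truth(df, truth)
                 for e, df in per_engine.items()}
        bench["consensus"] = ev.benchmark_vs_truth(cons, truth)
        print(f"{tag} vs implanted truth:")
        for name, b in bench.items():
            print(f"  {name:>14}: sensitivity {b['sensitivity']:.2f} "
                  f"observed FDR {b['observed_fdr']:.2f}")
        with open(out / f"{tag}_benchmark.json", "w") as fh:
            json.dump(bench, fh, indent=2, default=float)
    metrics = pd.concat(records, ignore_index=True)
    metrics.to_csv(out / "tool_metrics.tsv", sep="\t", index=False)
    agg = ev.aggregate_metrics(metrics)
    agg.to_csv(out / "tool_metrics_aggregate.tsv", sep="\t", index=False)
    print(agg.to_string(index=False))


if __name__ == "__main__":
    main()
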