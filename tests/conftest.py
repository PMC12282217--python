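import numpy as np
import pandas as pd
import pytest

from consenda.io_profiles import FeatureTable, SampleMetadata
from consenda import synthetic_data as sd


@pytest.fixture
def taxonomy_tsv(tmp_path):
    """A merged taxonomy table with 5 rank strings across 3 levels
    (1 kingdom, 2 phyla, 2 SGBs); kingdom rows sum to 100 per sample."""
    lines = [
        "clade_name\tS1\tS2\tS3",
        "k__Bacteria\t100.0\t100.0\t100.0",
        "k__Bacteria|p__Proteobacteria\t60.0\t20.0\t50.0",
        "k__Bacteria|p__Firmicutes\t40.0\t80.0\t50.0",
        "k__Bacteria|p__Proteobacteria|c__Gamma|o__Ent|f__EntF|g__Esch|s__Esch_coli|t__SGB10068\t60.0\t20.0\t50.0",
        "k__Bacteria|p__Firmicutes|c__Bacilli|o__Lact|f__Strep|g__Strep|s__Strep_oralis|t__SGB8130\t40.0\t80.0\t50.0",
    ]
    path = tmp_path / "merged_taxonomy.tsv"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def pathway_tsv(tmp_path):
    lines = [
        "# Pathway\tS1\tS2\tS3",
        "UNMAPPED\t500.0\t400.0\t300.0",
        "UNINTEGRATED\t50.0\t40.0\t30.0",
        "PWY-1: synthesis one\t100.0\t10.0\t20.0",
        "PWY-1: synthesis one|g__Esch.s__Esch_coli\t60.0\t5.0\t10.0",
        "PWY-1: synthesis one|g__Strep.s__Strep_oralis\t30.0\t3.0\t8.0",
        "PWY-1: synthesis one|unclassified\t10.0\t2.0\t2.0",
        "PWY-2: synthesis two\t0.0\t0.0\t0.0",
        "PWY-2: synthesis two|g__Esch.s__Esch_coli\t0.0\t0.0\t0.0",
        "PWY-2: synthesis two|g__Strep.s__Strep_oralis\t0.0\t0.0\t0.0",
        "PWY-2: synthesis two|unclassified\t0.0\t0.0\t0.0",
    ]
    path = tmp_path / "pathways.tsv"
    path.write_text("\n".join(lines) + "\n")
    return path


def make_table(values, sample_ids=None, feature_ids=None, unit="count", level="sgb"):
    values = np.asarray(values, dtype=float)
    sample_ids = sample_ids or [f"S{i+1}" for i in range(values.shape[0])]
    feature_ids = feature_ids or [f"F{j+1}" for j in range(values.shape[1])]
    return FeatureTable(pd.DataFrame(values, index=sample_ids, columns=feature_ids),
                        unit=unit, level=level)


def make_meta(sample_ids, groups, subjects=None, timepoints=None,
              library_sizes=None, bmi=None):
    n = len(sample_ids)
    df = pd.DataFrame({
        "subject_id": subjects or list(sample_ids),
        "group": groups,
        "timepoint": timepoints or ["early"] * n,
        "library_size": library_sizes or [100_000] * n,
    }, index=pd.Index(sample_ids, name="sample_id"))
    if bmi is not None:
        df["bmi"] = bmi
    return SampleMetadata(df)


@pytest.fixture
def two_group_cohort():
    """Unpaired 15 vs 15 cohort, 60 features, 3 implanted 8-fold effects."""
    cfg = sd.SimConfig(n_features=60, n_subjects_per_group=15, paired_fraction=0,
                       n_diff=3, seed=11)
    return sd.simulate_cohort(cfg)


@pytest.fixture
def null_cohort():
    cfg = sd.SimConfig(n_features=60, n_subjects_per_group=12, paired_fraction=0,
                       n_diff=0, seed=5)
    return sd.simulate_cohort(cfg)
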