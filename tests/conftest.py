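import numpy as np
import pandas as pd
import pytest

from visscreen.vis_calling import LocusSampleMatrix


def make_matrix(counts: dict[str, dict[str, int]], samples: pd.DataFrame,
                min_reads_detect: int = 1) -> LocusSampleMatrix:
    """Build a LocusSampleMatrix directly from per-locus read counts.

    ``counts``: locus_id -> {sample_id: reads}; missing samples are 0.
    """
    if "sample_id" in samples.columns:
        samples = samples.set_index("sample_id")
    tab = (
        pd.DataFrame(counts).T.reindex(columns=samples.index).fillna(0).astype(int)
    )
    loci = pd.DataFrame(
        {
            "chromosome": "chr1",
            "start": np.arange(len(tab)) * 10_000,
            "end": np.arange(len(tab)) * 10_000 + 100,
            "representative_position": np.arange(len(tab)) * 10_000 + 50,
            "n_reads": tab.sum(axis=1),
            "n_plus": tab.sum(axis=1),
            "n_minus": 0,
        },
        index=tab.index,
    )
    loci.index.name = "locus_id"
    totals = tab.sum(axis=0).replace(0, 1)
    return LocusSampleMatrix(
        loci=loci,
        samples=samples,
        read_counts=tab,
        rpm=tab * 1e6 / totals,
        detected=tab >= min_reads_detect,
        min_reads_detect=min_reads_detect,
    )


def sample_frame(spec: list[tuple[str, str, str]]) -> pd.DataFrame:
    """Samples from (sample_id, treatment, replicate) triples."""
    return pd.DataFrame(
        [
            {
                "sample_id": sid,
                "treatment": treatment,
                "biological_replicate": rep,
                "timepoint_months": 1,
            }
            for sid, treatment, rep in spec
        ]
    ).set_index("sample_id")


@pytest.fixture
def two_group_samples() -> pd.DataFrame:
    spec = [(f"NC_{r}_{i}", "NC", r) for r in ("pLN1", "pLN2") for i in range(3)]
    spec += [(f"fulv_{r}_{i}", "fulvestrant", r) for r in ("pLN1", "pLN2") for i in range(3)]
    return sample_frame(spec)
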