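import numpy as np
import pandas as pd
import pytest

from cnax.genome import FeatureAnnotation, ProbeTable


@pytest.fixture
def small_features() -> FeatureAnnotation:
    """Hand-placed genes on two chromosomes for interval tests."""
    rows = [
        ("g1", "chr1", 100, 200, "gene"),
        ("g2", "chr1", 400, 600, "gene"),
        ("g3", "chr1", 700, 900, "gene"),
        ("g4", "chr2", 50, 150, "gene"),
    ]
    return FeatureAnnotation(
        pd.DataFrame(rows, columns=["id", "chrom", "start", "end", "feature_class"])
    )


@pytest.fixture
def probe_table() -> ProbeTable:
    rows = [
        (f"p{i}", "chr1", 10 + 20 * i, "cgh") for i in range(5)
    ] + [(f"q{i}", "chr2", 15 + 30 * i, "cgh") for i in range(4)]
    return ProbeTable(pd.DataFrame(rows, columns=["id", "chrom", "pos", "array_type"]))


def random_features(rng: np.random.Generator, n: int, chroms=("chr1", "chr2", "chr3"),
                    size: int = 10_000) -> FeatureAnnotation:
    starts = rng.integers(0, size - 10, size=n)
    lengths = rng.integers(1, 500, size=n)
    df = pd.DataFrame(
        {
            "id": [f"f{i}" for i in range(n)],
            "chrom": rng.choice(chroms, size=n),
            "start": starts,
            "end": np.minimum(starts + lengths, size),
            "feature_class": "gene",
        }
    )
    return FeatureAnnotation(df)
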