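import numpy as np
import pandas as pd
import pytest

from locusweave.sumstats import SUMSTAT_COLUMNS


def make_sumstats(rows: list[dict]) -> pd.DataFrame:
    """Canonical sumstats frame from partial row dicts (defaults filled in)."""
    defaults = {
        "variant_id": "rs1", "chrom": "1", "pos": 100, "effect_allele": "A",
        "other_allele": "G", "beta": 0.1, "se": 0.05, "pvalue": 0.05,
        "eaf": 0.3, "n": 1000, "info": np.nan,
    }
    full = []
    for i, r in enumerate(rows):
        d = dict(defaults)
        d["variant_id"] = f"rs{i + 1}"
        d["pos"] = 100 + i * 1000
        d.update(r)
        full.append(d)
    return pd.DataFrame(full, columns=SUMSTAT_COLUMNS)


@pytest.fixture
def sumstats_file(tmp_path):
    """Write a sumstats frame to a TSV and return the path."""

    def _write(df: pd.DataFrame, name: str = "ss.tsv"):
        path = tmp_path / name
        df.to_csv(path, sep="\t", index=False)
        return path

    return _write


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
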