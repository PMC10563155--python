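import numpy as np
import pandas as pd
import pytest

from acquant.quant import QuantTable


def make_table(values: dict[str, list], *, protein_id=None, n_peptides=5,
               is_contaminant=False, is_ligand=False, level="protein",
               is_log2=True, index=None) -> QuantTable:
    """Build a small QuantTable from per-sample value lists (NaN = missing)."""
    frame = pd.DataFrame(values, dtype=float)
    if index is not None:
        frame.index = pd.Index(index, name="feature_id")
    else:
        frame.index = pd.Index([f"P{i + 1}" for i in range(len(frame))], name="feature_id")
    n = len(frame)

    def expand(value, default):
        if value is None:
            value = default
        return list(value) if isinstance(value, (list, tuple, pd.Series)) else [value] * n

    meta = pd.DataFrame({
        "protein_id": expand(protein_id, list(frame.index)),
        "n_peptides": expand(n_peptides, 5),
        "is_contaminant": expand(is_contaminant, False),
        "is_ligand": expand(is_ligand, False),
    }, index=frame.index)
    return QuantTable(meta, frame, level=level, is_log2=is_log2)


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)
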