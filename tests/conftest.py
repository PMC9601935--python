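import numpy as np
import pytest

from gamlp.data_io import CleanDataset
from gamlp.synthetic import make_separable


def write_csv(path, text):
    path.write_text(text.strip() + "\n")
    return str(path)


@pytest.fixture
def toy_csv(tmp_path):
    """A 5-row UCI-dialect table: 4 factors, 4 targets, one missing cell."""
    text = """\
f1,f2,f3,f4,Hinselmann,Schiller,Cytology,Biopsy
20,1,0,3.5,0,0,0,0
31,0,1,?,0,1,0,1
45,1,0,2.0,1,0,0,0
18,0,0,0.0,0,0,1,0
52,1,1,9.0,0,1,0,1
"""
    return write_csv(tmp_path / "toy.csv", text)


def separable_dataset(n_rows=400, margin=6.0, seed=0) -> CleanDataset:
    """A CleanDataset wrapper around two separable clouds, one per target."""
    X, y = make_separable(n_rows, n_factors=2, margin=margin, seed=seed)
    targets = {t: y for t in ("Hinselmann", "Schiller", "Cytology", "Biopsy")}
    return CleanDataset(X=X, y=targets, retained_factor_ids=[1, 2],
                        factor_names=["f1", "f2"])
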