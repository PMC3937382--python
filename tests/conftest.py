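import numpy as np
import pytest

from kinscan.io_formats import AMINO_ACIDS, ProteinSequence
from kinscan.profile_model import ProfileModel, build_profile
from kinscan.synthetic_data import default_templates


@pytest.fixture(scope="session")
def templates():
    tk, tkl, fslk = default_templates()
    return {"TK": tk, "TKL": tkl, "FslK": fslk}


@pytest.fixture(scope="session")
def template_profiles(templates):
    """Single-seed profiles built from each group's consensus."""
    return {
        name: build_profile(t.to_msa(), pseudocount_weight=1.0, cutoff_bits=20.0, name=name)
        for name, t in templates.items()
    }


def random_profile(rng, n_columns, gap_open=None, gap_extend=None) -> ProfileModel:
    """A profile with arbitrary per-column scores, for DP stress tests."""
    log_odds = np.zeros((n_columns, 21))
    log_odds[:, :20] = rng.uniform(-4.0, 5.0, size=(n_columns, 20))
    return ProfileModel(
        name="random",
        log_odds=log_odds,
        background=np.full(20, 1 / 20),
        gap_open=float(rng.uniform(2.0, 12.0)) if gap_open is None else gap_open,
        gap_extend=float(rng.uniform(0.5, 2.0)) if gap_extend is None else gap_extend,
        cutoff_bits=0.0,
    )


def random_sequence(rng, length) -> ProteinSequence:
    residues = "".join(AMINO_ACIDS[int(c)] for c in rng.integers(0, 20, size=length))
    return ProteinSequence(f"r{length}", residues if residues else "A")
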