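import numpy as np
import pytest
from hypothesis import settings

from mydgf_nmr.io_formats import AssignmentLabel, Condition, Peak, PeakList

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def make_peaklist(shifts, condition=None, heights=None):
    """PeakList from {label_text: (delta_N, delta_H)}."""
    from mydgf_nmr.io_formats import parse_assignment_label

    condition = condition or Condition(name="test")
    peaks = []
    for i, (text, (dn, dh)) in enumerate(shifts.items()):
        h = heights[text] if heights else None
        peaks.append(Peak(parse_assignment_label(text), delta_N=dn, delta_H=dh, height=h))
    return PeakList(condition, peaks)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_peaklist():
    return make_peaklist(
        {
            "E34N-H": (118.2, 8.11),
            "H49N-H": (120.5, 8.20),
            "W77N-H": (129.1, 10.05),
            "W95N-H": (122.7, 9.30),
        }
    )


@pytest.fixture
def toy_ensemble():
    """Two-model, two-residue toy ensemble with backbone + CB atoms."""
    from mydgf_nmr.io_formats import AtomRecord, StructureEnsemble

    atoms = [
        AtomRecord("A", res, "ALA", name, element=name[0])
        for res in (49, 50)
        for name in ("N", "CA", "C", "O", "CB")
    ]
    rng = np.random.default_rng(7)
    base = rng.uniform(-5, 5, size=(len(atoms), 3))
    return StructureEnsemble(atoms, np.stack([base, base + 0.1]))
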