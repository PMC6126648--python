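import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=DeprecationWarning)

from loopgraft.fixtures import (FixtureSpec, build_ground_truth,  # noqa: E402
                                make_fixture)


@pytest.fixture(scope="session")
def default_spec():
    return FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def truth(default_spec):
    return build_ground_truth(default_spec)


@pytest.fixture(scope="session")
def fixture_set():
    """(truth, target, homologs, map, constructs) for a 4-residue gap."""
    spec = FixtureSpec(seed=3, homolog_mutations=2)
    return spec, make_fixture(spec)


def backbone_rmsd_over(truth, model, start, end):
    """Backbone RMSD between the truth and the model over construct
    positions [start, end] (0-based; truth numbering is pos + 1)."""
    tp = truth.chains[0].polymer()
    mp = model.chains[0].polymer()
    errs = []
    for pos in range(start, end + 1):
        rt = tp[pos]
        rm = next((r for r in mp if r.number == rt.number), None)
        if rm is None:
            return None
        for nm in ("N", "CA", "C", "O"):
            if rm.atom(nm) is None:
                return None
            errs.append(np.linalg.norm(rt.atom(nm).pos - rm.atom(nm).pos))
    return float(np.sqrt(np.mean(np.square(errs))))
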