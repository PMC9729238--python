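import numpy as np
import pytest

from tfx import synth
from tfx.funnel import FunnelConfig, run_funnel
from tfx.structio import Atom, Structure


@pytest.fixture(scope="session")
def spec7():
    return synth.SynthSpec(seed=7)


@pytest.fixture(scope="session")
def toy(spec7):
    return synth.make_toy_complex(spec7)


@pytest.fixture(scope="session")
def exp_map(toy, spec7):
    return synth.make_experimental_map(toy, spec7)


@pytest.fixture(scope="session")
def pose_ensemble(toy, spec7):
    """(poses, planted_id) for the 1-planted + 99-decoy benchmark."""
    return synth.make_pose_ensemble(toy.true_pose, 99, spec7)


@pytest.fixture(scope="session")
def funnel_cfg(toy):
    return FunnelConfig(required_residues=toy.required_residues)


@pytest.fixture(scope="session")
def funnel_report(toy, exp_map, pose_ensemble, funnel_cfg):
    """Funnel run on the benchmark, shared across tests (expensive)."""
    poses, _ = pose_ensemble
    return run_funnel(poses, toy.ensembles(), exp_map, funnel_cfg)


def make_atom(serial, name, element, res_name, res_id, chain, xyz, **kw):
    from tfx import _chem

    kw.setdefault("vdw_radius", _chem.vdw_radius(element))
    kw.setdefault("mhp_const", _chem.mhp_constant(res_name, name, element))
    return Atom(serial, name, element, res_name, res_id, chain,
                np.asarray(xyz, dtype=float), **kw)


def simple_structure(entries):
    """Structure from (name, element, res_name, res_id, chain, xyz) tuples."""
    return Structure([make_atom(i + 1, *e) for i, e in enumerate(entries)])
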