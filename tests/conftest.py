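"""Shared fixtures: synthetic complexes and their extracted statistics.

Heavy objects (trajectory + full statistics pass) are session-scoped so the
suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from mdpharm.interface_analysis import (
    extract_site_statistics,
    pocket_from_reference,
    representative_frame,
)
from mdpharm.pharmacophore_model import (
    assign_positions,
    build_master,
    threshold_sites,
)
from mdpharm.synthetic_fixtures import (
    FixtureSpec,
    default_fixture_plan,
    make_complex_trajectory,
)


@pytest.fixture(scope="session")
def recovery_fixture():
    """Planted-statistics fixture: all five site classes at 80% occupancy."""
    spec = FixtureSpec(
        pocket_plan=default_fixture_plan(0.8), n_frames=20, seed=1
    )
    traj, gt = make_complex_trajectory(spec)
    return spec, traj, gt


@pytest.fixture(scope="session")
def recovery_extraction(recovery_fixture):
    spec, traj, gt = recovery_fixture
    pocket = pocket_from_reference(
        traj.topology, np.array(gt["reference_coords"])
    )
    stats, extras = extract_site_statistics(traj, pocket)
    return {
        "spec": spec,
        "traj": traj,
        "gt": gt,
        "pocket": pocket,
        "stats": stats,
        "extras": extras,
    }


@pytest.fixture(scope="session")
def master_fixture():
    """Fully-occupied fixture with its extracted master pharmacophore."""
    spec = FixtureSpec(
        pocket_plan=default_fixture_plan(1.0), n_frames=10, seed=2
    )
    traj, gt = make_complex_trajectory(spec)
    pocket = pocket_from_reference(
        traj.topology, np.array(gt["reference_coords"])
    )
    stats, _ = extract_site_statistics(traj, pocket)
    sites = threshold_sites(traj.topology, pocket, stats)
    rep = representative_frame(traj, pocket.residue_indices)
    frame = traj.frame(rep)
    features = assign_positions(sites, frame, pocket.pocket_center)
    master = build_master(features, frame)
    return {
        "spec": spec,
        "traj": traj,
        "gt": gt,
        "pocket": pocket,
        "frame": frame,
        "master": master,
    }
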