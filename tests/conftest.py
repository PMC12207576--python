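"""Shared fixtures: hand-built frames and brute-force distance oracles."""

from __future__ import annotations

import numpy as np
import pytest

from rplcpore.model import MoleculeRecord, SlitPoreFrame, Topology


def build_frame(
    particles: list[tuple[str, str, int, tuple[float, float, float]]],
    box=(4.0, 4.0, 12.0),
    surface_planes=(1.0, 11.0),
    time: float = 0.0,
) -> SlitPoreFrame:
    """Frame from (site_name, role, molecule_id, xyz) tuples."""
    return SlitPoreFrame(
        time=time,
        box=np.asarray(box, float),
        site_names=np.array([p[0] for p in particles]),
        roles=np.array([p[1] for p in particles]),
        molecule_ids=np.array([p[2] for p in particles]),
        positions=np.array([p[3] for p in particles], float),
        surface_planes=surface_planes,
    )


def simple_topology(frame: SlitPoreFrame, annotations: dict | None = None) -> Topology:
    """One MoleculeRecord per molecule id, optionally annotated.

    ``annotations`` maps molecule_id -> dict of MoleculeRecord kwargs
    (aromatic_rings, donor_ids, acceptor_ids, vector_tail_id, ...).
    """
    annotations = annotations or {}
    molecules = {}
    for mid in np.unique(frame.molecule_ids):
        ids = np.flatnonzero(frame.molecule_ids == mid).tolist()
        role = str(frame.roles[ids[0]])
        extra = annotations.get(int(mid), {})
        molecules[int(mid)] = MoleculeRecord(
            molecule_id=int(mid),
            compound=extra.pop("compound", role),
            role=role,
            particle_ids=ids,
            **extra,
        )
    return Topology(molecules=molecules)


def brute_min_image_distance(p, q, box, periodic_z=False) -> float:
    """Minimum distance over all 9 (or 27) periodic images — the oracle."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    box = np.asarray(box, float)
    z_images = (-1, 0, 1) if periodic_z else (0,)
    best = np.inf
    for ix in (-1, 0, 1):
        for iy in (-1, 0, 1):
            for iz in z_images:
                shift = np.array([ix * box[0], iy * box[1], iz * box[2]])
                best = min(best, float(np.linalg.norm(q + shift - p)))
    return best


def brute_count_within(center, points, cutoff, box, periodic_z=False) -> int:
    return sum(
        brute_min_image_distance(center, pt, box, periodic_z) <= cutoff for pt in points
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260917)
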