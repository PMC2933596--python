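"""12-moment molecular shape descriptors and Euclidean 3D similarity search.

A conformer's shape is summarised by the ultrafast-shape-recognition (USR)
signature: from each of four reference points — the centroid, the atom closest
to the centroid, the atom farthest from the centroid, and the atom farthest
from that atom — the set of all atom distances is reduced to three moments
(arithmetic mean, population standard deviation, and the signed cube root of
the population third central moment), giving 12 numbers that are invariant
under rigid motion of the molecule.  Shape similarity between two conformers
is the Euclidean distance between their 12-vectors (smaller = more similar).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

SHAPE_DESCRIPTOR_DIM = 12


@dataclass(frozen=True)
class Conformer:
    """One 3D structure: an ordered array of atom coordinates in Å."""

    compound_id: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.coords, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 1:
            raise InvalidInputError(
                f"conformer coordinates must be an (n>=1, 3) array, got shape {arr.shape}"
            )
        if not np.isfinite(arr).all():
            raise InvalidInputError("conformer coordinates must all be finite")
        arr.setflags(write=False)
        object.__setattr__(self, "coords", arr)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


def _moments(distances: np.ndarray) -> tuple[float, float, float]:
    # Population (not sample) moments; signed cube root preserves skew direction.
    # Cubes are formed by explicit multiplication: np.power is not exactly
    # antisymmetric, and the cube root amplifies any residue of a third moment
    # that should cancel to zero (e.g. two atoms, distances {-d, +d}).
    mean = float(distances.mean())
    centred = distances - mean
    var = float((centred * centred).mean())
    third = float((centred * centred * centred).mean())
    return mean, float(np.sqrt(var)), float(np.cbrt(third))


def usr_descriptor(conf: Conformer) -> np.ndarray:
    """The 12-value shape signature of a conformer.

    Reference points, in order: centroid; atom closest to the centroid; atom
    farthest from the centroid; atom farthest from that atom.  Ties on the
    reference-atom choice are broken by lowest atom index.  For each reference
    the distance set over all atoms yields (mean, std, cbrt of third central
    moment), concatenated into a vector of 12.
    """
    coords = conf.coords
    centroid = coords.mean(axis=0)
    d_centroid = np.linalg.norm(coords - centroid, axis=1)
    closest = coords[int(np.argmin(d_centroid))]
    farthest = coords[int(np.argmax(d_centroid))]
    d_farthest = np.linalg.norm(coords - farthest, axis=1)
    far_from_far = coords[int(np.argmax(d_farthest))]

    values: list[float] = []
    for ref in (centroid, closest, farthest, far_from_far):
        distances = np.linalg.norm(coords - ref, axis=1)
        values.extend(_moments(distances))
    return np.asarray(values, dtype=float)


def shape_distance(d1: np.ndarray, d2: np.ndarray) -> float:
    """Euclidean (L2) distance between two 12-value shape descriptors."""
    a = np.asarray(d1, dtype=float)
    b = np.asarray(d2, dtype=float)
    if a.shape != (SHAPE_DESCRIPTOR_DIM,) or b.shape != (SHAPE_DESCRIPTOR_DIM,):
        raise InvalidInputError(
            f"shape descriptors must have exactly {SHAPE_DESCRIPTOR_DIM} values"
        )
    return float(np.linalg.norm(a - b))


def _conformer_mapping(store: object) -> Mapping[str, Conformer]:
    if isinstance(store, Mapping):
        return store
    conformers = getattr(store, "conformers", None)
    if conformers is None:
        raise InvalidInputError(
            "search_3d needs a DataStore or a mapping of compound_id -> Conformer"
        )
    return conformers


def search_3d(query: Conformer, store: object, k: int) -> list[tuple[str, float]]:
    """The k nearest compounds to a query conformer by descriptor distance.

    Accepts a loaded :class:`~chemlinker.datastore.DataStore` or any mapping of
    compound_id to :class:`Conformer`.  Results ascend by distance with ties
    broken by compound_id; an empty store yields an empty list.
    """
    if k <= 0:
        raise InvalidInputError(f"k must be positive, got {k}")
    conformers = _conformer_mapping(store)
    if not conformers:
        return []
    q = usr_descriptor(query)
    cached: Mapping[str, np.ndarray] | None = getattr(store, "shape_descriptors", None)
    scored: list[tuple[str, float]] = []
    for compound_id, conf in conformers.items():
        desc = cached[compound_id] if cached is not None else usr_descriptor(conf)
        scored.append((compound_id, shape_distance(q, desc)))
    scored.sort(key=lambda t: (t[1], t[0]))
    return scored[:k]


def random_rigid_transform(
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random rotation matrix and a translation vector.

    Utility for invariance testing and fixture planting; the rotation comes
    from the QR decomposition of a Gaussian matrix with sign correction.
    """
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-10.0, 10.0, size=3)
    return q, t


def apply_rigid_transform(
    conf: Conformer, rotation: np.ndarray, translation: np.ndarray
) -> Conformer:
    return Conformer(conf.compound_id, conf.coords @ np.asarray(rotation).T + translation)
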