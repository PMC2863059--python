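"""Probability-weighted long-range contact descriptors.

The native topology of a protein is summarised from a residue-residue
contact probability map P (predicted from sequence by an upstream contact
predictor) by two descriptors:

* **LRCN** (long-range contact number) — the expected number of long-range
  contacts, ``Σ_{|i−j| ≥ s} P_ij / L^c`` with ``c = 1``;
* **LRCO** (long-range contact order) — the probability-weighted average
  sequence separation of long-range contacts,
  ``Σ_{|i−j| ≥ s} P_ij · |i−j| / L^c`` with ``c = 2``.

A pair counts once (unordered).  Defaults: contact distance threshold 8 Å,
minimum sequence separation s = 12.  On a binary {0,1} map these reduce
exactly to the classic binary-contact definitions.  The classic relative
contact order CO (all separations, normalized by L and by the total contact
mass) is provided for comparison, as are the structure-derived "real"
counterparts computed from Cα coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io_formats import ContactProbabilityMap, ValidationError

__all__ = [
    "ContactParams",
    "ContactDescriptorSet",
    "compute_lrcn",
    "compute_lrco",
    "compute_co",
    "real_contact_map",
    "binarize_map",
    "descriptor_set",
]


@dataclass(frozen=True)
class ContactParams:
    """Parameters of the contact descriptor definitions.

    distance_threshold
        Cα-Cα distance (Å) at or below which two residues are in contact
        (closed comparison: d ≤ threshold is a contact).
    min_separation
        Minimum sequence separation |i−j| for a pair to count as long-range.
    c_lrcn, c_lrco
        Length-normalization exponents for LRCN and LRCO.
    """

    distance_threshold: float = 8.0
    min_separation: int = 12
    c_lrcn: float = 1.0
    c_lrco: float = 2.0

    def __post_init__(self) -> None:
        if self.distance_threshold <= 0:
            raise ValidationError("distance_threshold must be > 0")
        if self.min_separation < 1:
            raise ValidationError("min_separation must be >= 1")
        if self.c_lrcn < 0 or self.c_lrco < 0:
            raise ValidationError("normalization exponents must be >= 0")


@dataclass
class ContactDescriptorSet:
    """Contact descriptors for one protein (``r_*`` are structure-derived)."""

    lrcn: float
    lrco: float
    co: float
    r_lrcn: Optional[float] = None
    r_lrco: Optional[float] = None


def _check_map(cmap: ContactProbabilityMap, length: int) -> None:
    if cmap.n != length:
        raise ValidationError(f"contact map dimension {cmap.n} != sequence length {length}")
    if length < 1:
        raise ValidationError("sequence length must be >= 1")


def _separation_matrix(n: int) -> np.ndarray:
    idx = np.arange(n)
    return np.abs(idx[:, None] - idx[None, :])


def compute_lrcn(
    cmap: ContactProbabilityMap, length: int, params: ContactParams = ContactParams()
) -> float:
    """Expected long-range contact count, normalized by ``L^c_lrcn``."""
    _check_map(cmap, length)
    sep = _separation_matrix(length)
    mask = np.triu(sep >= params.min_separation)
    total = float(np.sum(cmap.probs[mask]))
    return total / length**params.c_lrcn


def compute_lrco(
    cmap: ContactProbabilityMap, length: int, params: ContactParams = ContactParams()
) -> float:
    """Probability-weighted long-range contact order, normalized by ``L^c_lrco``."""
    _check_map(cmap, length)
    sep = _separation_matrix(length)
    mask = np.triu(sep >= params.min_separation)
    total = float(np.sum((cmap.probs * sep)[mask]))
    return total / length**params.c_lrco


def compute_co(
    cmap: ContactProbabilityMap, length: int, params: ContactParams = ContactParams()
) -> float:
    """Relative contact order over all separations: ``Σ P_ij·|i−j| / (L·Σ P_ij)``.

    Returns 0 for a map with no contact mass.
    """
    _check_map(cmap, length)
    sep = _separation_matrix(length)
    mask = np.triu(sep >= 1)
    mass = float(np.sum(cmap.probs[mask]))
    if mass == 0.0:
        return 0.0
    weighted = float(np.sum((cmap.probs * sep)[mask]))
    return weighted / (length * mass)


def real_contact_map(
    ca_coords: Sequence[Optional[tuple[float, float, float]]],
    params: ContactParams = ContactParams(),
) -> ContactProbabilityMap:
    """Binary contact map from Cα coordinates at the distance threshold.

    ``p(i, j) = 1`` iff the Euclidean Cα-Cα distance is ≤ the threshold
    (closed comparison).  Pairs involving a missing coordinate are treated
    as non-contacting.
    """
    n = len(ca_coords)
    present = np.array([c is not None for c in ca_coords])
    if int(present.sum()) < 2:
        raise ValidationError("need at least 2 non-missing CA coordinates")
    coords = np.array([c if c is not None else (0.0, 0.0, 0.0) for c in ca_coords], dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=-1))
    contacts = (dist <= params.distance_threshold).astype(float)
    observable = np.outer(present, present)
    contacts = contacts * observable
    np.fill_diagonal(contacts, 0.0)
    return ContactProbabilityMap(n=n, probs=contacts)


def binarize_map(cmap: ContactProbabilityMap, threshold: float) -> ContactProbabilityMap:
    """Binary map with p' = 1 where p ≥ threshold, else 0 (for baselines)."""
    if not (0.0 <= threshold <= 1.0):
        raise ValidationError(f"binarization threshold {threshold} outside [0, 1]")
    binary = (cmap.probs >= threshold).astype(float)
    np.fill_diagonal(binary, 0.0)
    return ContactProbabilityMap(n=cmap.n, probs=binary)


def descriptor_set(
    cmap: ContactProbabilityMap,
    length: int,
    ca_coords: Optional[Sequence[Optional[tuple[float, float, float]]]] = None,
    params: ContactParams = ContactParams(),
) -> ContactDescriptorSet:
    """All contact descriptors for one protein, structure-derived ones if possible."""
    result = ContactDescriptorSet(
        lrcn=compute_lrcn(cmap, length, params),
        lrco=compute_lrco(cmap, length, params),
        co=compute_co(cmap, length, params),
    )
    if ca_coords is not None:
        rmap = real_contact_map(ca_coords, params)
        result.r_lrcn = compute_lrcn(rmap, length, params)
        result.r_lrco = compute_lrco(rmap, length, params)
    return result
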