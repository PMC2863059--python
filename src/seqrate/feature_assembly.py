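"""Assembly of model-specific feature vectors, with feature scaling.

The two-stage predictor uses three distinct feature sets:

* ``CLASSIFIER`` (25 features): sequence length, LRCO, LRCN, α-helical
  content, β-sheet content, and the 20 amino-acid composition frequencies.
* ``REG_TWO_STATE`` (4 features): LRCO, LRCN, α-helical content, β-sheet
  content.  Length is a weak rate predictor for two-state folders and the
  20-dim composition is excluded from regression to avoid over-fitting.
* ``REG_MULTI_STATE`` (5 features, default): the two-state set plus length —
  length is the dominant rate predictor for multi-state folders.  A config
  switch (``multistate_features='length_contacts_only'``) drops the
  secondary-structure contents instead, the alternative reading under which
  α/β contents are excluded from the multi-state model.

Coil content is never included in any model (it correlates negligibly with
rates in both kinetic classes).  An optional precomputed geometric-contact
scalar can be appended to any role.

Scaling parameters are learned from training rows only; min-max to [0, 1]
is the default (sensible for RBF kernels mixing length ~10² with
compositions ~10⁻¹).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
import numpy as np

from .contact_features import ContactParams, compute_lrcn, compute_lrco
from .io_formats import CANONICAL_RESIDUES, ProteinRecord, ValidationError
from .sequence_features import aa_composition, ss_composition

__all__ = [
    "ModelRole",
    "FeatureConfig",
    "FeatureVector",
    "ScalingParams",
    "assemble",
    "assemble_matrix",
    "fit_scaling",
]


class ModelRole(Enum):
    CLASSIFIER = "classifier"
    REG_TWO_STATE = "reg_two_state"
    REG_MULTI_STATE = "reg_multi_state"


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-set configuration shared by training and prediction.

    multistate_features
        ``'with_ss'`` (default): multi-state regressor uses length + LRCO +
        LRCN + helix + sheet.  ``'length_contacts_only'``: length + LRCO +
        LRCN only.
    use_gc
        Append the precomputed geometric-contact scalar to every role.
    scaling
        ``'minmax'`` (default), ``'zscore'`` or ``'none'``.
    """

    multistate_features: str = "with_ss"
    use_gc: bool = False
    scaling: str = "minmax"
    contact_params: ContactParams = field(default_factory=ContactParams)

    def __post_init__(self) -> None:
        if self.multistate_features not in ("with_ss", "length_contacts_only"):
            raise ValidationError(f"bad multistate_features: {self.multistate_features!r}")
        if self.scaling not in ("minmax", "zscore", "none"):
            raise ValidationError(f"bad scaling method: {self.scaling!r}")

    def feature_names(self, role: ModelRole) -> list[str]:
        if role is ModelRole.CLASSIFIER:
            names = ["L", "LRCO", "LRCN", "helix", "sheet"] + [
                f"comp_{a}" for a in CANONICAL_RESIDUES
            ]
        elif role is ModelRole.REG_TWO_STATE:
            names = ["LRCO", "LRCN", "helix", "sheet"]
        else:
            if self.multistate_features == "with_ss":
                names = ["L", "LRCO", "LRCN", "helix", "sheet"]
            else:
                names = ["L", "LRCO", "LRCN"]
        if self.use_gc:
            names = names + ["GC"]
        return names


@dataclass
class FeatureVector:
    names: list[str]
    values: np.ndarray
    role: ModelRole

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise ValidationError("feature names/values length mismatch")


def assemble(record: ProteinRecord, role: ModelRole, config: FeatureConfig = FeatureConfig()) -> FeatureVector:
    """Build the feature vector for one protein under the given model role."""
    names = config.feature_names(role)
    if record.contact_map is None:
        raise ValidationError(f"record {record.id!r}: contact map required for feature {names[0]}")
    needs_ss = any(n in ("helix", "sheet") for n in names)
    if needs_ss and record.ss_string is None:
        raise ValidationError(f"record {record.id!r}: SS string required for helix/sheet content")
    if config.use_gc and record.gc_value is None:
        raise ValidationError(f"record {record.id!r}: gc_value required when GC feature enabled")

    L = record.length
    lrco = compute_lrco(record.contact_map, L, config.contact_params)
    lrcn = compute_lrcn(record.contact_map, L, config.contact_params)
    parts: dict[str, float] = {"L": float(L), "LRCO": lrco, "LRCN": lrcn}
    if needs_ss:
        ss = ss_composition(record.ss_string)
        parts["helix"] = ss.helix
        parts["sheet"] = ss.sheet
    if role is ModelRole.CLASSIFIER:
        comp = aa_composition(record.sequence, strict=False)
        for a, f in comp.freqs.items():
            parts[f"comp_{a}"] = f
    if config.use_gc:
        parts["GC"] = float(record.gc_value)
    values = np.array([parts[n] for n in names])
    return FeatureVector(names=names, values=values, role=role)


def assemble_matrix(
    records: list[ProteinRecord], role: ModelRole, config: FeatureConfig = FeatureConfig()
) -> tuple[np.ndarray, list[str]]:
    """Stack per-record feature vectors into an (n, p) matrix."""
    vectors = [assemble(r, role, config) for r in records]
    names = vectors[0].names
    return np.vstack([v.values for v in vectors]), names


@dataclass
class ScalingParams:
    """Per-feature scaling learned from training rows only.

    Constant columns map to 0 under both methods (the divisor is guarded
    to 1).
    """

    method: str
    offset: np.ndarray  # min (minmax) or mean (zscore)
    scale: np.ndarray  # guarded range (minmax) or guarded sd (zscore)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.method == "none":
            return X.copy()
        return (X - self.offset) / self.scale


def fit_scaling(matrix: np.ndarray, method: str = "minmax") -> ScalingParams:
    """Learn scaling parameters from a training feature matrix."""
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    if X.size == 0 or X.shape[0] < 1:
        raise ValidationError("cannot fit scaling on an empty matrix")
    if method == "minmax":
        lo = X.min(axis=0)
        rng = X.max(axis=0) - lo
        rng[rng == 0] = 1.0
        return ScalingParams(method=method, offset=lo, scale=rng)
    if method == "zscore":
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        return ScalingParams(method=method, offset=mean, scale=sd)
    if method == "none":
        p = X.shape[1]
        return ScalingParams(method=method, offset=np.zeros(p), scale=np.ones(p))
    raise ValidationError(f"unknown scaling method {method!r}")
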