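"""Desk-scale synthetic folding benchmarks.

Real folding-rate compilations (tens of proteins with experimentally
measured rates, plus predictor-estimated contact maps and secondary
structure) cannot be bundled, so this module generates datasets with the
same statistical structure:

* a Cα backbone per protein, built as a confined pseudo-self-avoiding
  random walk with 3.8 Å steps — compactness (the confinement radius) is
  set per kinetic class so two-state folders carry a denser long-range
  contact network than the larger multi-state folders;
* a "real" binary contact map from that geometry (8 Å, Cα-Cα), and a
  "predicted" probability map derived from it by corrupting the truth the
  way an upstream contact predictor would: real contacts get high but noisy
  probabilities, a fraction are missed, and a small rate of spurious pairs
  is injected — so estimated and structure-derived descriptors correlate
  strongly but imperfectly;
* class-specific secondary-structure strings (segment sampling around a
  class SS profile) and sequences (class-tilted residue frequencies);
* planted log10 folding rates: a class-specific linear-plus-mild-quadratic
  function of the protein's own descriptors (computed from the emitted
  predicted map), plus Gaussian noise.  Signs mirror the known kinetic
  biases: rates fall with contact order/number for two-state folders, and
  fall steeply with chain length for multi-state folders.

Everything is deterministic given (config, seed): running the generator
twice with the same config writes byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .contact_features import ContactParams, compute_lrcn, compute_lrco
from .io_formats import (
    CANONICAL_RESIDUES,
    ContactProbabilityMap,
    KineticLabel,
    ProteinRecord,
    RateDatasetTable,
    ValidationError,
    write_contact_map,
    write_rate_table,
    write_ss_string,
)
from .sequence_features import ss_composition

__all__ = [
    "ClassProfile",
    "RateModel",
    "SyntheticConfig",
    "SyntheticBenchmark",
    "generate_contact_map",
    "generate_protein_record",
    "generate_benchmark",
    "DEFAULT_CONFIG",
]

_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

CA_STEP = 3.8  # Å, consecutive Cα-Cα distance
MIN_NONLOCAL_DIST = 3.6  # Å, soft self-avoidance radius


@dataclass(frozen=True)
class RateModel:
    """Planted mapping from descriptors to log10 folding rate.

    ``linear`` keys are descriptor names; ``L100`` is chain length / 100 so
    all coefficients act on O(1) quantities.  One mild quadratic term keeps
    the true relationship nonlinear, so a kernel regressor has genuine
    headroom over an ordinary linear fit.
    """

    intercept: float
    linear: dict[str, float]
    quad_feature: str = "LRCO"
    quad_center: float = 0.0
    quad_coef: float = 0.0

    def evaluate(self, feats: dict[str, float]) -> float:
        y = self.intercept
        for name, coef in self.linear.items():
            y += coef * feats[name]
        y += self.quad_coef * (feats[self.quad_feature] - self.quad_center) ** 2
        return y


@dataclass(frozen=True)
class ClassProfile:
    """Generation parameters for one kinetic class."""

    length_range: tuple[int, int]
    contact_density: float  # drives backbone compactness / contact density
    long_range_bias: float  # scales predicted-map mass at separation >= 12
    helix_frac: float
    sheet_frac: float
    aa_tilt: dict[str, float]  # additive tilt on uniform residue frequencies
    rate_model: RateModel


# Two-state folders: small (40-110 aa), compact, sheet-rich; rates fall with
# long-range contact order and contact number, fall with helix content and
# rise with sheet content.  Multi-state folders: large (90-300 aa), less
# dense long-range networks, helix-rich; rates fall steeply with length.
# Intercepts and spreads put log10 k_f in the span seen in experimental
# compilations (roughly -2 .. 4 for two-state, -5 .. 1 for multi-state,
# signal sd ~ 1.1-1.3 per class).  Descriptor centering constants were
# fixed once from a pilot run of this generator (LRCO mean/sd ~ 0.44/0.18
# and 0.44/0.15, LRCN ~ 1.04/0.41 and 1.38/0.38, L100 ~ 0.74/0.20 and
# 1.92/0.56 for the two classes) and are frozen.
TWO_STATE_PROFILE = ClassProfile(
    length_range=(40, 110),
    contact_density=0.080,
    long_range_bias=1.0,
    helix_frac=0.28,
    sheet_frac=0.32,
    aa_tilt={"G": 0.012, "N": 0.012, "D": 0.010, "S": 0.010, "T": 0.008,
             "L": -0.012, "I": -0.012, "K": -0.010, "E": -0.010, "R": -0.008},
    rate_model=RateModel(
        intercept=4.8,
        linear={"LRCO": -6.0, "LRCN": -1.0, "helix": -1.5, "sheet": 1.5},
        quad_feature="LRCO",
        quad_center=0.45,
        quad_coef=8.0,
    ),
)

MULTI_STATE_PROFILE = ClassProfile(
    length_range=(90, 300),
    contact_density=0.045,
    long_range_bias=1.0,
    helix_frac=0.46,
    sheet_frac=0.12,
    aa_tilt={"L": 0.012, "I": 0.010, "K": 0.010, "E": 0.012, "R": 0.008,
             "G": -0.012, "N": -0.010, "D": -0.010, "S": -0.010, "T": -0.008},
    rate_model=RateModel(
        intercept=3.6,
        linear={"L100": -2.0, "LRCO": -2.0, "LRCN": -0.5},
        quad_feature="L100",
        quad_center=1.9,
        quad_coef=0.8,
    ),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Stated world of the synthetic benchmark.

    Defaults emulate the documented structure of the reference benchmark: a
    ~61:39 two-state:multi-state mix, overlapping class length ranges, and
    rate-descriptor relationships whose signs follow the known kinetic
    biases.  ``noise_sd`` is the Gaussian sd added to planted log10 rates.
    """

    n_proteins: int = 80
    two_state_fraction: float = 37 / 61  # reference benchmark class mix
    noise_sd: float = 0.3
    seed: int = 0
    with_structures: bool = True
    with_gc: bool = False
    two_state: ClassProfile = field(default_factory=lambda: TWO_STATE_PROFILE)
    multi_state: ClassProfile = field(default_factory=lambda: MULTI_STATE_PROFILE)
    contact_params: ContactParams = field(default_factory=ContactParams)

    def __post_init__(self) -> None:
        if self.n_proteins < 6:
            raise ValidationError("n_proteins must be >= 6")
        if not (0.0 < self.two_state_fraction < 1.0):
            raise ValidationError("two_state_fraction must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        for prof in (self.two_state, self.multi_state):
            if prof.length_range[0] < 15:
                raise ValidationError("minimum length is 15 (separation-12 pairs must exist)")
            if not (0.0 < prof.contact_density < 1.0):
                raise ValidationError("contact_density must be in (0, 1)")


DEFAULT_CONFIG = SyntheticConfig()


def generate_contact_map(
    L: int, density: float, long_range_bias: float, seed: int
) -> ContactProbabilityMap:
    """Standalone random contact probability map (no backbone geometry).

    Each unordered pair is a contact with probability ``density`` (scaled by
    ``long_range_bias`` for pairs at separation >= 12); contacts draw a
    probability uniformly from [0.3, 1].  ``long_range_bias = 0`` therefore
    zeroes every long-range pair and ``density = 0`` yields an empty map.
    """
    if L < 15:
        raise ValidationError("L must be >= 15")
    if not (0.0 <= density < 1.0):
        raise ValidationError("density must be in [0, 1)")
    if long_range_bias < 0:
        raise ValidationError("long_range_bias must be >= 0")
    rng = np.random.default_rng(seed)
    probs = np.zeros((L, L))
    idx = np.arange(L)
    sep = np.abs(idx[:, None] - idx[None, :])
    iu, ju = np.triu_indices(L, k=1)
    q = np.full(iu.shape, density)
    q[sep[iu, ju] >= 12] = min(1.0, density * long_range_bias)
    hit = rng.random(iu.shape) < q
    values = np.where(hit, rng.uniform(0.3, 1.0, size=iu.shape), 0.0)
    probs[iu, ju] = values
    probs[ju, iu] = values
    return ContactProbabilityMap(n=L, probs=np.round(probs, 6))


def _confined_walk(L: int, density: float, rng: np.random.Generator) -> np.ndarray:
    """Pseudo-self-avoiding random walk inside a sphere.

    The confinement radius scales as L^(1/3) (globular packing) and shrinks
    with the target contact density, so denser classes fold back onto
    themselves more often.
    """
    radius = 4.0 * L ** (1 / 3) * (0.08 / density) ** (1 / 3)
    coords = np.zeros((L, 3))
    for i in range(1, L):
        best_cand, best_score = None, -np.inf
        for _ in range(40):
            step = rng.normal(size=3)
            if np.linalg.norm(coords[i - 1]) > radius:
                # bias the step back toward the interior of the sphere
                step = step - 1.5 * coords[i - 1] / np.linalg.norm(coords[i - 1])
            step *= CA_STEP / np.linalg.norm(step)
            cand = coords[i - 1] + step
            if i >= 2:
                clearance = float(np.linalg.norm(coords[: i - 1] - cand, axis=1).min())
            else:
                clearance = np.inf
            inside = np.linalg.norm(cand) <= radius
            if clearance >= MIN_NONLOCAL_DIST and inside:
                best_cand = cand
                break
            score = min(clearance, MIN_NONLOCAL_DIST) - (0.0 if inside else 1.0)
            if score > best_score:
                best_cand, best_score = cand, score
        coords[i] = best_cand
    return np.round(coords, 3)


def _predicted_from_real(
    real: np.ndarray, sep: np.ndarray, bias: float, rng: np.random.Generator
) -> np.ndarray:
    """Corrupt a binary contact map into predictor-like probabilities."""
    L = real.shape[0]
    iu, ju = np.triu_indices(L, k=1)
    truth = real[iu, ju] > 0
    p = np.zeros(iu.shape)
    # true contacts: mostly high probabilities, 15% missed
    hit = rng.random(iu.shape) < 0.85
    p[truth & hit] = np.clip(rng.normal(0.75, 0.12, size=int((truth & hit).sum())), 0.05, 1.0)
    p[truth & ~hit] = rng.uniform(0.0, 0.10, size=int((truth & ~hit).sum()))
    # non-contacts: sparse false positives at low-to-mid probability
    fp = (~truth) & (rng.random(iu.shape) < 0.02)
    p[fp] = rng.uniform(0.05, 0.45, size=int(fp.sum()))
    longr = sep[iu, ju] >= 12
    p[longr] = np.clip(p[longr] * bias, 0.0, 1.0)
    probs = np.zeros((L, L))
    probs[iu, ju] = p
    probs[ju, iu] = p
    return np.round(probs, 6)


def _ss_string(L: int, profile: ClassProfile, rng: np.random.Generator) -> str:
    """Segment-sampled secondary-structure string near the class profile."""
    coil = max(1e-9, 1.0 - profile.helix_frac - profile.sheet_frac)
    mean_len = {"H": 9.0, "E": 5.5, "C": 4.5}
    weights = np.array(
        [profile.helix_frac / mean_len["H"], profile.sheet_frac / mean_len["E"], coil / mean_len["C"]]
    )
    weights /= weights.sum()
    out: list[str] = []
    while len(out) < L:
        kind = ("H", "E", "C")[rng.choice(3, p=weights)]
        if kind == "H":
            seg = int(rng.integers(4, 16))
        elif kind == "E":
            seg = int(rng.integers(3, 9))
        else:
            seg = int(rng.integers(2, 8))
        out.extend(kind * seg)
    return "".join(out[:L])


def _sequence(L: int, profile: ClassProfile, rng: np.random.Generator) -> str:
    freqs = np.full(20, 0.05)
    for aa, tilt in profile.aa_tilt.items():
        freqs[CANONICAL_RESIDUES.index(aa)] += tilt
    freqs = np.clip(freqs, 1e-4, None)
    freqs /= freqs.sum()
    return "".join(rng.choice(list(CANONICAL_RESIDUES), size=L, p=freqs))


def _rate_features(record: ProteinRecord, params: ContactParams) -> dict[str, float]:
    ss = ss_composition(record.ss_string)
    return {
        "L100": record.length / 100.0,
        "LRCO": compute_lrco(record.contact_map, record.length, params),
        "LRCN": compute_lrcn(record.contact_map, record.length, params),
        "helix": ss.helix,
        "sheet": ss.sheet,
    }


def generate_protein_record(
    pid: str,
    label: KineticLabel,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> ProteinRecord:
    """Generate one protein: geometry, maps, SS, sequence and planted rate."""
    profile = config.two_state if label is KineticLabel.TWO_STATE else config.multi_state
    lo, hi = profile.length_range
    L = int(rng.integers(lo, hi + 1))
    sequence = _sequence(L, profile, rng)
    ss = _ss_string(L, profile, rng)

    coords = _confined_walk(L, profile.contact_density, rng)
    idx = np.arange(L)
    sep = np.abs(idx[:, None] - idx[None, :])
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=-1))
    real = (dist <= config.contact_params.distance_threshold).astype(float)
    np.fill_diagonal(real, 0.0)
    probs = _predicted_from_real(real, sep, profile.long_range_bias, rng)
    cmap = ContactProbabilityMap(n=L, probs=probs)

    record = ProteinRecord(
        id=pid,
        sequence=sequence,
        ss_string=ss,
        contact_map=cmap,
        ca_coords=[tuple(c) for c in coords] if config.with_structures else None,
    )
    feats = _rate_features(record, config.contact_params)
    noise = rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
    record.log_rate = profile.rate_model.evaluate(feats) + noise
    record.kinetic_label = label
    if config.with_gc:
        # geometric-contact stand-in: a packing count anti-correlated with rate
        record.gc_value = float(max(0.0, 30.0 - 6.0 * record.log_rate + rng.normal(0.0, 3.0)))
    return record


@dataclass
class SyntheticBenchmark:
    table: RateDatasetTable
    records: list[ProteinRecord]
    out_dir: Optional[Path] = None


def _write_pdb(path: Path, record: ProteinRecord) -> None:
    lines = []
    for i, (aa, xyz) in enumerate(zip(record.sequence, record.ca_coords), start=1):
        x, y, z = xyz
        lines.append(
            f"ATOM  {i:5d}  CA  {_AA3[aa]} A{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def generate_benchmark(
    config: SyntheticConfig = DEFAULT_CONFIG, out_dir: Optional[str | Path] = None
) -> SyntheticBenchmark:
    """Generate the benchmark; optionally write all per-protein files.

    When ``out_dir`` is given, writes ``proteins.fasta``, ``rates.tsv`` and
    per-protein ``<id>.cmap`` / ``<id>.ss`` / ``<id>.pdb`` files in the
    dialects the readers in :mod:`seqrate.io_formats` expect.
    """
    rng = np.random.default_rng(config.seed)
    n_two = int(round(config.n_proteins * config.two_state_fraction))
    n_two = min(max(n_two, 3), config.n_proteins - 3)
    labels = [KineticLabel.TWO_STATE] * n_two + [KineticLabel.MULTI_STATE] * (
        config.n_proteins - n_two
    )
    records = []
    for k, label in enumerate(labels):
        prefix = "TS" if label is KineticLabel.TWO_STATE else "MS"
        records.append(generate_protein_record(f"{prefix}{k:03d}", label, config, rng))
    table = RateDatasetTable(
        rows=[(r.id, r.log_rate, r.kinetic_label, r.gc_value) for r in records]
    )
    out_path: Optional[Path] = None
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        fasta = []
        for r in records:
            fasta.append(f">{r.id}")
            fasta.extend(r.sequence[i : i + 60] for i in range(0, r.length, 60))
            write_contact_map(out_path / f"{r.id}.cmap", r.contact_map)
            write_ss_string(out_path / f"{r.id}.ss", r.ss_string)
            if r.ca_coords is not None:
                _write_pdb(out_path / f"{r.id}.pdb", r)
        (out_path / "proteins.fasta").write_text("\n".join(fasta) + "\n")
        write_rate_table(out_path / "rates.tsv", table)
    return SyntheticBenchmark(table=table, records=records, out_dir=out_path)
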