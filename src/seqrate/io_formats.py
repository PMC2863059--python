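"""Readers and writers for every external representation the tool touches.

Formats handled here:

* FASTA protein sequences (via Biopython's ``SeqIO``),
* single-line 3-state secondary-structure strings over ``{H, E, C}``,
* residue-residue contact probability maps in the CASP-RR text dialect
  (``i j p`` lines, 1-based indices, ``i < j``),
* Cα coordinates from PDB ``ATOM`` records (via ``Bio.PDB``),
* the tab-separated rate dataset table
  (``id\\tlog_rate\\tkinetic_label[\\tgc_value]``).

All external indexing is 1-based over residues; internally maps are dense
0-based NumPy arrays.  Experimental folding rates are exchanged as
``log10(k_f / sec^-1)``; a converter from natural-log inputs is provided
because some published case-study values are quoted in natural log.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser

__all__ = [
    "FormatError",
    "ValidationError",
    "KineticLabel",
    "ContactProbabilityMap",
    "ProteinRecord",
    "RateDatasetTable",
    "CANONICAL_RESIDUES",
    "read_fasta",
    "read_ss_string",
    "write_ss_string",
    "read_contact_map",
    "write_contact_map",
    "read_pdb_ca",
    "read_rate_table",
    "write_rate_table",
    "ln_to_log10",
]

# The 20 canonical one-letter residue codes, alphabetical; this ordering is
# the fixed column order of every composition feature vector downstream.
CANONICAL_RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_RESIDUES)

SS_ALPHABET = frozenset("HEC")


class FormatError(ValueError):
    """A file is structurally unreadable in its declared format."""


class ValidationError(ValueError):
    """A file parsed but violates a domain invariant."""


class KineticLabel(Enum):
    """Binary folding kinetic mechanism of a protein."""

    TWO_STATE = "two_state"
    MULTI_STATE = "multi_state"

    @classmethod
    def parse(cls, text: str) -> "KineticLabel":
        """Normalize a label string case-insensitively.

        Accepts spellings like ``Two-State``, ``two_state``, ``MULTI STATE``
        and ``three-state`` (multi-state folders are sometimes called
        three-state in the literature).
        """
        key = text.strip().lower().replace("-", "_").replace(" ", "_")
        if key in ("two_state", "twostate", "2_state"):
            return cls.TWO_STATE
        if key in ("multi_state", "multistate", "three_state", "3_state"):
            return cls.MULTI_STATE
        raise ValidationError(f"unrecognized kinetic label: {text!r}")


@dataclass
class ContactProbabilityMap:
    """Symmetric per-residue-pair contact probabilities for one protein.

    ``probs`` is a dense ``(n, n)`` float array with ``probs[i, j]`` the
    probability (0-based internally) that residues ``i+1`` and ``j+1`` are
    within the contact distance threshold in the native structure.  The
    diagonal is zero and the matrix is symmetric by construction.
    """

    n: int
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (self.n, self.n):
            raise ValidationError(
                f"contact map shape {self.probs.shape} does not match n={self.n}"
            )
        if np.any(self.probs < 0) or np.any(self.probs > 1):
            raise ValidationError("contact probabilities must lie in [0, 1]")
        if not np.allclose(self.probs, self.probs.T):
            raise ValidationError("contact map must be symmetric")
        np.fill_diagonal(self.probs, 0.0)

    @classmethod
    def zeros(cls, n: int) -> "ContactProbabilityMap":
        return cls(n=n, probs=np.zeros((n, n)))

    @classmethod
    def from_pairs(
        cls, n: int, pairs: Sequence[tuple[int, int, float]]
    ) -> "ContactProbabilityMap":
        """Build a map from 1-based ``(i, j, p)`` triples, mirroring for symmetry."""
        probs = np.zeros((n, n))
        for i, j, p in pairs:
            if not (1 <= i <= n and 1 <= j <= n):
                raise ValidationError(f"residue index out of range: ({i}, {j}) with n={n}")
            if i == j:
                raise ValidationError(f"self-contact ({i}, {i}) is not allowed")
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"probability {p} for pair ({i}, {j}) outside [0, 1]")
            probs[i - 1, j - 1] = p
            probs[j - 1, i - 1] = p
        return cls(n=n, probs=probs)

    def get(self, i: int, j: int) -> float:
        """Probability for the 1-based residue pair ``(i, j)``."""
        return float(self.probs[i - 1, j - 1])


@dataclass
class ProteinRecord:
    """One protein: sequence plus whatever per-protein inputs are available."""

    id: str
    sequence: str
    ss_string: Optional[str] = None
    contact_map: Optional[ContactProbabilityMap] = None
    ca_coords: Optional[list[Optional[tuple[float, float, float]]]] = None
    log_rate: Optional[float] = None
    kinetic_label: Optional[KineticLabel] = None
    gc_value: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        if self.ss_string is not None and len(self.ss_string) != len(self.sequence):
            raise ValidationError(
                f"record {self.id!r}: SS string length {len(self.ss_string)} "
                f"!= sequence length {len(self.sequence)}"
            )
        if self.contact_map is not None and self.contact_map.n != len(self.sequence):
            raise ValidationError(
                f"record {self.id!r}: contact map dimension {self.contact_map.n} "
                f"!= sequence length {len(self.sequence)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class RateDatasetTable:
    """Tabular mapping of protein ids to experimental rates and kinetic labels."""

    rows: list[tuple[str, float, KineticLabel, Optional[float]]]
    source: Optional[str] = None

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.rows]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate ids in rate table: {dup}")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.rows]


def _validate_sequence(seq: str, record_id: str, strict: bool) -> str:
    seq = seq.upper()
    if strict:
        for pos, ch in enumerate(seq, start=1):
            if ch not in _CANONICAL_SET:
                raise ValidationError(
                    f"record {record_id!r}: illegal residue {ch!r} at position {pos}"
                )
    return seq


def read_fasta(path: str | Path, strict: bool = True) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    In strict mode (default) any character outside the 20 canonical
    one-letter codes raises :class:`ValidationError` naming the record and
    position; in lenient mode non-canonical characters are kept and handled
    downstream (excluded from composition).
    """
    path = Path(path)
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = _validate_sequence(str(entry.seq), entry.id, strict)
        records.append(ProteinRecord(id=entry.id, sequence=seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def read_ss_string(path: str | Path, expected_length: Optional[int] = None) -> str:
    """Read a single-line secondary-structure string over ``{H, E, C}``."""
    text = Path(path).read_text().strip()
    if not text:
        raise FormatError(f"{path}: empty secondary-structure file")
    for pos, ch in enumerate(text, start=1):
        if ch not in SS_ALPHABET:
            raise ValidationError(
                f"{path}: illegal secondary-structure character {ch!r} at position {pos}"
            )
    if expected_length is not None and len(text) != expected_length:
        raise ValidationError(
            f"{path}: SS string length {len(text)} != expected {expected_length}"
        )
    return text


def write_ss_string(path: str | Path, ss: str) -> None:
    Path(path).write_text(ss + "\n")


def read_contact_map(path: str | Path, n: int) -> ContactProbabilityMap:
    """Read a CASP-RR-style contact probability file.

    Lines are ``i j p`` (whitespace separated, 1-based, ``i < j``); optional
    header lines starting with a non-digit are skipped.  Unlisted pairs have
    probability 0; symmetry is enforced by mirroring.
    """
    path = Path(path)
    pairs: dict[tuple[int, int], float] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or not line[0].isdigit():
            continue  # header / comment line
        parts = line.split()
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: expected 'i j p', got {raw!r}")
        try:
            i, j, p = int(parts[0]), int(parts[1]), float(parts[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: unparseable contact line {raw!r}") from exc
        if i >= j:
            raise ValidationError(f"{path}:{lineno}: require i < j, got ({i}, {j})")
        if j > n:
            raise ValidationError(f"{path}:{lineno}: residue index {j} exceeds n={n}")
        if not (0.0 <= p <= 1.0):
            raise ValidationError(f"{path}:{lineno}: probability {p} outside [0, 1]")
        if (i, j) in pairs and pairs[(i, j)] != p:
            raise ValidationError(
                f"{path}:{lineno}: conflicting duplicate pair ({i}, {j}): "
                f"{pairs[(i, j)]} vs {p}"
            )
        pairs[(i, j)] = p
    return ContactProbabilityMap.from_pairs(n, [(i, j, p) for (i, j), p in pairs.items()])


def write_contact_map(path: str | Path, cmap: ContactProbabilityMap) -> None:
    """Write the nonzero upper triangle as ``i j p`` lines with 6 decimals."""
    lines = []
    iu, ju = np.triu_indices(cmap.n, k=1)
    for i, j in zip(iu, ju):
        p = cmap.probs[i, j]
        if p > 0:
            lines.append(f"{i + 1} {j + 1} {p:.6f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_pdb_ca(
    path: str | Path, chain: str = "A"
) -> list[Optional[tuple[float, float, float]]]:
    """Extract ordered Cα coordinates for one chain from a PDB file.

    Only the first model is read.  Alternate locations are resolved by
    highest occupancy, ties by first-seen.  Residues without a Cα atom
    contribute a ``None`` entry.  Water and hetero residues are skipped.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("s", str(path))
    models = list(structure.get_models())
    if not models:
        raise FormatError(f"{path}: no ATOM records / models found")
    model = models[0]
    chain_ids = [c.id for c in model.get_chains()]
    if chain not in chain_ids:
        raise KeyError(f"{path}: chain {chain!r} not present (found {chain_ids})")
    coords: list[Optional[tuple[float, float, float]]] = []
    for residue in model[chain]:
        hetflag = residue.id[0]
        if hetflag != " ":
            continue
        ca = None
        if "CA" in residue:
            atom = residue["CA"]
            if atom.is_disordered():
                alts = sorted(
                    atom.disordered_get_list(),
                    key=lambda a: -(a.get_occupancy() or 0.0),
                )
                atom = alts[0]
            ca = tuple(float(x) for x in atom.get_coord())
        coords.append(ca)
    if not coords:
        raise FormatError(f"{path}: chain {chain!r} has no standard residues")
    return coords


def ln_to_log10(value: float) -> float:
    """Convert a natural-log folding rate to base-10 log."""
    return value / math.log(10.0)


def read_rate_table(path: str | Path, rate_base: str = "log10") -> RateDatasetTable:
    """Read the TSV rate table (``id``, ``log_rate``, ``kinetic_label``, optional ``gc_value``).

    ``rate_base='ln'`` converts natural-log rates to base-10 on input.
    """
    if rate_base not in ("log10", "ln"):
        raise ValueError(f"rate_base must be 'log10' or 'ln', got {rate_base!r}")
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty rate table")
    header = lines[0].rstrip("\n").split("\t")
    required = ["id", "log_rate", "kinetic_label"]
    if header[: len(required)] != required:
        raise FormatError(f"{path}: bad header {header!r}; expected {required} [+ gc_value]")
    has_gc = len(header) > 3 and header[3] == "gc_value"
    rows: list[tuple[str, float, KineticLabel, Optional[float]]] = []
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: expected at least 3 columns")
        pid = parts[0].strip()
        try:
            rate = float(parts[1])
        except ValueError as exc:
            raise ValidationError(f"{path}:{lineno}: unparseable rate {parts[1]!r}") from exc
        if rate_base == "ln":
            rate = ln_to_log10(rate)
        label = KineticLabel.parse(parts[2])
        gc: Optional[float] = None
        if has_gc and len(parts) > 3 and parts[3].strip() != "":
            gc = float(parts[3])
        rows.append((pid, rate, label, gc))
    return RateDatasetTable(rows=rows, source=str(path))


def write_rate_table(path: str | Path, table: RateDatasetTable) -> None:
    has_gc = any(r[3] is not None for r in table.rows)
    header = "id\tlog_rate\tkinetic_label" + ("\tgc_value" if has_gc else "")
    lines = [header]
    for pid, rate, label, gc in table.rows:
        row = f"{pid}\t{rate:.6f}\t{label.value}"
        if has_gc:
            row += "\t" + (f"{gc:.6f}" if gc is not None else "")
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")
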