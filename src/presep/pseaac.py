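"""Pseudo amino acid composition (PseAAC) encoding of protein sequences.

A protein of length L is mapped to a fixed-length feature vector combining
the 20 relative amino-acid frequencies f_u with sequence-order correlation
factors computed from normalized physicochemical scales (:mod:`presep.aa_properties`):

Type I (parallel correlation), dimension 20 + lam:
    theta_j = mean over the L-j lag-j residue pairs of
              (1/n_props) * sum_k [H_k(R_{i+j}) - H_k(R_i)]^2
    x_u     = f_u / (1 + w * sum_j theta_j)            for u = 1..20
    x_{20+j} = w * theta_j / (1 + w * sum_j theta_j)

Type II (series correlation), dimension 20 + i*lam for i property scales:
    tau_{j,k} = mean over lag-j pairs of H_k(R_i) * H_k(R_{i+j})
    components ordered lag-major: (j=1, k=1..i), (j=2, k=1..i), ...
    same composition-plus-correlation normalization, with the tau values
    (which may be negative) in place of the theta values.

Both encodings sum to 1. Sequences shorter than lam+1 are handled with an
effective rank lam_eff = min(lam, L-1): lags beyond lam_eff contribute a
correlation factor of exactly 0, and the output dimension is unchanged, so
feature matrices stay rectangular across mixed-length inputs (required by
the terminal-truncation scan, where 17-residue windows are encoded with
lam = 19).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .aa_properties import AA_INDEX, AMINO_ACIDS, SCALE_NAMES, PropertyTable, load_property_table
from .exceptions import (
    AlphabetError,
    DegenerateDenominatorError,
    LagError,
    PresepError,
    SequenceError,
    TooShortError,
)

_DENOM_TOL = 1e-12


class PseAACType(enum.Enum):
    """Encoding family: parallel (I) or series (II) correlation."""

    TYPE_I = "I"
    TYPE_II = "II"


@dataclass(frozen=True)
class Truncation:
    """Keep only the first (N) or last (C) ``k`` residues before encoding."""

    terminal: str  # "N" or "C"
    k: int

    def __post_init__(self):
        if self.terminal not in ("N", "C"):
            raise ValueError("terminal must be 'N' or 'C'")
        if self.k < 1:
            raise ValueError("truncation length k must be >= 1")


@dataclass(frozen=True)
class PseAACParams:
    """Encoding configuration.

    Parameters
    ----------
    mode : PseAACType
        TYPE_I (one joint correlation function over all selected scales) or
        TYPE_II (one correlation track per scale).
    w : float
        Weight of the correlation factors relative to composition, 0 < w <= 1.
    lam : int
        Maximum correlation rank (lag), >= 1.
    properties : tuple of str
        Ordered subset of the six scale names; defaults to all six.
    truncation : Truncation or None
        Optional terminal window applied before encoding.
    nonstandard : str
        Policy for residues outside the 20-letter alphabet: "strict"
        (default, raise) or "drop" (silently remove).
    """

    mode: PseAACType = PseAACType.TYPE_I
    w: float = 0.05
    lam: int = 19
    properties: tuple[str, ...] = tuple(SCALE_NAMES)
    truncation: Truncation | None = None
    nonstandard: str = "strict"

    def __post_init__(self):
        if not 0 < self.w <= 1:
            raise ValueError(f"w must be in (0, 1], got {self.w}")
        if self.lam < 1:
            raise ValueError(f"lam must be >= 1, got {self.lam}")
        if len(self.properties) < 1:
            raise ValueError("at least one property scale is required")
        if self.nonstandard not in ("strict", "drop"):
            raise ValueError("nonstandard policy must be 'strict' or 'drop'")
        object.__setattr__(self, "properties", tuple(self.properties))
        if isinstance(self.mode, str):  # accept "I"/"II" for convenience
            object.__setattr__(self, "mode", PseAACType(self.mode))

    @property
    def dimension(self) -> int:
        """20 + lam (Type I) or 20 + i*lam (Type II)."""
        if self.mode is PseAACType.TYPE_I:
            return 20 + self.lam
        return 20 + len(self.properties) * self.lam

    def with_truncation(self, terminal: str, k: int) -> "PseAACParams":
        return replace(self, truncation=Truncation(terminal, k))

    def to_dict(self) -> dict:
        d = {
            "mode": self.mode.value,
            "w": self.w,
            "lam": self.lam,
            "properties": list(self.properties),
            "nonstandard": self.nonstandard,
        }
        if self.truncation is not None:
            d["truncation"] = {"terminal": self.truncation.terminal, "k": self.truncation.k}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PseAACParams":
        trunc = d.get("truncation")
        return cls(
            mode=PseAACType(d["mode"]),
            w=d["w"],
            lam=d["lam"],
            properties=tuple(d["properties"]),
            truncation=Truncation(**trunc) if trunc else None,
            nonstandard=d.get("nonstandard", "strict"),
        )


@dataclass(frozen=True)
class FeatureVector:
    """A PseAAC vector paired with its sequence id and parameters."""

    seq_id: str
    values: np.ndarray
    params: PseAACParams

    @property
    def dimension(self) -> int:
        return self.values.shape[0]


def validate_sequence(seq: str, params: PseAACParams | None = None) -> str:
    """Uppercase, strip whitespace and terminal '*', apply the residue policy.

    Returns a sequence over the 20 standard one-letter codes. Under the
    strict policy (default) a non-standard residue raises
    :class:`AlphabetError` naming the 1-based position and symbol; under the
    drop policy offending residues are removed. Sequences shorter than 2
    residues after cleaning raise :class:`TooShortError`.
    """
    policy = params.nonstandard if params is not None else "strict"
    s = "".join(seq.split()).upper().rstrip("*")
    if not s:
        raise TooShortError("empty sequence")
    if policy == "strict":
        for pos, ch in enumerate(s, start=1):
            if ch not in AA_INDEX:
                raise AlphabetError(ch, pos)
        cleaned = s
    else:
        cleaned = "".join(ch for ch in s if ch in AA_INDEX)
    if len(cleaned) < 2:
        raise TooShortError(
            f"sequence has {len(cleaned)} usable residue(s); need at least 2"
        )
    return cleaned


def truncate(seq: str, terminal: str, k: int) -> str:
    """First (N) or last (C) ``k`` residues; the full sequence when k >= L."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if terminal == "N":
        return seq[:k]
    if terminal == "C":
        return seq[-k:]
    raise ValueError("terminal must be 'N' or 'C'")


def _indices(seq: str) -> np.ndarray:
    try:
        return np.fromiter((AA_INDEX[c] for c in seq), dtype=np.intp, count=len(seq))
    except KeyError as e:  # pragma: no cover - callers validate first
        raise SequenceError(f"non-standard residue {e.args[0]!r}") from None


def theta_type1(
    seq: str, j: int, table: PropertyTable, properties: Sequence[str] | None = None
) -> float:
    """Type I correlation factor theta_j for one lag.

    Average over the L-j lag-j residue pairs of the multi-property squared
    difference (1/n_props) * sum_k [H_k(R_{i+j}) - H_k(R_i)]^2. Non-negative
    and invariant under sequence reversal.
    """
    L = len(seq)
    if not 1 <= j <= L - 1:
        raise LagError(f"lag {j} out of range for length-{L} sequence")
    H = table.matrix(properties)
    idx = _indices(seq)
    d = H[:, idx[j:]] - H[:, idx[:-j]]
    return float(np.mean(d * d))


def tau_type2(seq: str, j: int, table: PropertyTable, scale: str) -> float:
    """Type II correlation factor tau for one (lag, scale) pair.

    Mean over lag-j pairs of H_k(R_i) * H_k(R_{i+j}); may be negative.
    """
    L = len(seq)
    if not 1 <= j <= L - 1:
        raise LagError(f"lag {j} out of range for length-{L} sequence")
    h = table.matrix([scale])[0]
    idx = _indices(seq)
    v = h[idx]
    return float(np.mean(v[:-j] * v[j:]))


def _encode_indices(
    idx: np.ndarray, mode: PseAACType, w: float, lam: int, H: np.ndarray
) -> np.ndarray:
    """Encode an index array; lam = 0 degenerates to plain composition."""
    L = idx.shape[0]
    f = np.bincount(idx, minlength=20).astype(float) / L
    n_props = H.shape[0]
    lam_eff = min(lam, L - 1)

    if mode is PseAACType.TYPE_I:
        corr = np.zeros(lam)
        for j in range(1, lam_eff + 1):
            d = H[:, idx[j:]] - H[:, idx[:-j]]
            corr[j - 1] = np.mean(d * d)
    else:
        corr2 = np.zeros((lam, n_props))
        Hs = H[:, idx]
        for j in range(1, lam_eff + 1):
            corr2[j - 1] = np.mean(Hs[:, :-j] * Hs[:, j:], axis=1)
        corr = corr2.ravel()  # lag-major: all scales at lag 1, then lag 2, ...

    denom = 1.0 + w * corr.sum()  # sum(f) == 1 by construction
    if mode is PseAACType.TYPE_II and abs(denom) <= _DENOM_TOL:
        raise DegenerateDenominatorError(
            "Type II normalising denominator vanished; correlation factors "
            "cancel the composition mass"
        )
    return np.concatenate([f, w * corr]) / denom


def encode(
    seq: str, params: PseAACParams, table: PropertyTable | None = None, seq_id: str = ""
) -> FeatureVector:
    """Encode one sequence into its PseAAC feature vector.

    The sequence is validated (residue policy from ``params``), the optional
    terminal truncation applied, and the Type I/II vector computed. The
    result has exactly ``params.dimension`` components summing to 1.
    """
    if table is None:
        table = load_property_table()
    cleaned = validate_sequence(seq, params)
    if params.truncation is not None:
        cleaned = truncate(cleaned, params.truncation.terminal, params.truncation.k)
        if len(cleaned) < 2:
            raise TooShortError("truncation window leaves fewer than 2 residues")
    H = table.matrix(params.properties)
    values = _encode_indices(_indices(cleaned), params.mode, params.w, params.lam, H)
    return FeatureVector(seq_id=seq_id, values=values, params=params)


def feature_names(params: PseAACParams) -> list[str]:
    """Column names: the 20 residue codes, then the correlation components.

    Type I: ``theta_1 .. theta_lam``. Type II, lag-major: ``tau_1_<scale>``
    for every configured scale, then lag 2, and so on.
    """
    names = list(AMINO_ACIDS)
    if params.mode is PseAACType.TYPE_I:
        names += [f"theta_{j}" for j in range(1, params.lam + 1)]
    else:
        names += [
            f"tau_{j}_{p}"
            for j in range(1, params.lam + 1)
            for p in params.properties
        ]
    return names


def encode_batch(
    records: Iterable[tuple[str, str]],
    params: PseAACParams,
    table: PropertyTable | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Encode (id, sequence) records into a feature matrix.

    Row order preserves input order; row r equals ``encode(records[r])``.
    Returns ``(matrix of shape (n, params.dimension), ids)``. Any failing
    record aborts the batch with a :class:`PresepError` listing the
    offending ids.
    """
    if table is None:
        table = load_property_table()
    rec = list(records)
    if not rec:
        return np.empty((0, params.dimension)), []
    rows, ids, failures = [], [], []
    for seq_id, seq in rec:
        try:
            rows.append(encode(seq, params, table, seq_id=seq_id).values)
            ids.append(seq_id)
        except PresepError as e:
            failures.append((seq_id, str(e)))
    if failures:
        detail = "; ".join(f"{i}: {m}" for i, m in failures)
        raise SequenceError(f"{len(failures)} record(s) failed encoding: {detail}")
    return np.vstack(rows), ids
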