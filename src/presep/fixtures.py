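"""Synthetic two-class protein sequence sets with plantable signal.

Real curated secretion datasets are external resources; these generators
produce labeled sequence sets whose class signal is fully under the test's
control, so every pipeline stage (encoding, CV, sweep, terminal scan) can be
exercised and planted effects recovered without any download.

Two kinds of signal are available, separately or combined:

* composition bias ``delta`` — the positive class receives ``delta`` extra
  probability mass spread evenly over a designated hydrophobic residue set,
  withdrawn evenly from the remaining residues. This is exactly the kind of
  signal the amino-acid-composition half of a PseAAC vector detects. The
  default set is the branched-chain aliphatic trio I, L, V: concentrating
  the bias on three residues makes the default ``delta = 0.15`` fixture
  strongly separated (each enriched residue's frequency doubles relative to
  the uniform background), the regime the signal-recovery checks assume.
* a periodic motif — copies of a short motif written into one class at a
  fixed period, optionally restricted to the first k residues. Restricting
  the motif to the N-terminal region creates the N/C asymmetry a terminal
  scan should expose.

Background composition is uniform over the 20 residues by default so planted
signal is the only structure; a natural-abundance background is available.
Lengths are uniform over the configured range. Lengths, residues and motif
placement use separate RNG streams derived from the master seed, so changing
one knob leaves the other draws unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .aa_properties import AMINO_ACIDS
from .dataset import LabeledDataset, LabeledRecord, write_fasta, write_label_table
from .exceptions import PresepError
from .util import derive_seed

HYDROPHOBIC_SET_DEFAULT = "ILV"

#: Approximate Swiss-Prot residue frequencies (renormalised over 20 codes).
NATURAL_ABUNDANCE: dict[str, float] = {
    "A": 0.0826, "C": 0.0139, "D": 0.0546, "E": 0.0672, "F": 0.0387,
    "G": 0.0708, "H": 0.0228, "I": 0.0593, "K": 0.0580, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0475, "Q": 0.0393, "R": 0.0553,
    "S": 0.0660, "T": 0.0535, "V": 0.0687, "W": 0.0110, "Y": 0.0292,
}


@dataclass(frozen=True)
class MotifSignal:
    """A motif written periodically into sequences of one class.

    ``region`` limits planting to the first ``region`` residues (an
    N-terminal signal); ``None`` plants throughout the sequence.
    """

    motif: str
    period: int
    target_class: int = 1
    region: int | None = None

    def __post_init__(self):
        if not self.motif or any(c not in AMINO_ACIDS for c in self.motif):
            raise PresepError("motif must be a non-empty standard-residue string")
        if self.period < len(self.motif):
            raise PresepError("period must be >= motif length")
        if self.target_class not in (0, 1):
            raise PresepError("target_class must be 0 or 1")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic labeled sequence set."""

    n_pos: int = 200
    n_neg: int = 200
    length_range: tuple[int, int] = (80, 200)
    delta: float = 0.15
    enriched_residues: str = HYDROPHOBIC_SET_DEFAULT
    background: str = "uniform"  # or "natural"
    motif: MotifSignal | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_pos < 1 or self.n_neg < 1:
            raise PresepError("need at least one sequence per class")
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise PresepError(f"bad length range {self.length_range}")
        if self.background not in ("uniform", "natural"):
            raise PresepError("background must be 'uniform' or 'natural'")
        if not set(self.enriched_residues) <= set(AMINO_ACIDS):
            raise PresepError("enriched_residues must be standard residues")
        # validity of the biased distribution is checked in class_distribution

    def class_distribution(self, label: int) -> np.ndarray:
        """Residue sampling probabilities for one class, AMINO_ACIDS order."""
        if self.background == "uniform":
            p = np.full(20, 1 / 20)
        else:
            p = np.array([NATURAL_ABUNDANCE[a] for a in AMINO_ACIDS])
            p = p / p.sum()
        if label == 1 and self.delta != 0:
            enriched = np.array([a in self.enriched_residues for a in AMINO_ACIDS])
            n_in = int(enriched.sum())
            n_out = 20 - n_in
            if n_in == 0 or n_out == 0:
                raise PresepError("enriched set must be a proper subset of residues")
            p = p + np.where(enriched, self.delta / n_in, -self.delta / n_out)
        if (p < 0).any() or abs(p.sum() - 1) > 1e-9:
            raise PresepError(
                f"delta={self.delta} makes the class distribution degenerate"
            )
        return p

    def to_dict(self) -> dict:
        d = asdict(self)
        d["length_range"] = list(self.length_range)
        return d


def _plant_motif(residues: np.ndarray, motif: MotifSignal) -> None:
    """Overwrite residue indices in place with periodic motif copies."""
    aa_idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    m = np.array([aa_idx[c] for c in motif.motif], dtype=residues.dtype)
    limit = len(residues) if motif.region is None else min(motif.region, len(residues))
    start = 0
    while start + len(m) <= limit:
        residues[start : start + len(m)] = m
        start += motif.period


def generate(spec: FixtureSpec) -> LabeledDataset:
    """Generate the labeled dataset a :class:`FixtureSpec` describes.

    Deterministic under ``spec.seed``; the class ratio is exactly as
    requested and lengths are uniform over ``spec.length_range``.
    """
    rng_len = np.random.default_rng(derive_seed(spec.seed, "lengths"))
    rng_res = np.random.default_rng(derive_seed(spec.seed, "residues"))

    lo, hi = spec.length_range
    records: list[LabeledRecord] = []
    for label, n, prefix in ((1, spec.n_pos, "POS"), (0, spec.n_neg, "NEG")):
        p = spec.class_distribution(label)
        lengths = rng_len.integers(lo, hi + 1, size=n)
        for i, L in enumerate(lengths, start=1):
            idx = rng_res.choice(20, size=int(L), p=p)
            if spec.motif is not None and spec.motif.target_class == label:
                _plant_motif(idx, spec.motif)
            seq = "".join(AMINO_ACIDS[k] for k in idx)
            records.append(LabeledRecord(f"{prefix}{i:04d}", seq, label))
    return LabeledDataset(
        records=records,
        provenance=f"synthetic fixture seed={spec.seed}",
        filter_log={"input": len(records), "short": 0, "retained": len(records)},
    )


def imbalanced_preset(seed: int = 0, delta: float = 0.10) -> FixtureSpec:
    """A fixture mirroring the realistic class imbalance: 136 secretion-
    positive vs 957 negative sequences, moderate compositional signal."""
    return FixtureSpec(n_pos=136, n_neg=957, delta=delta, seed=seed)


def to_files(dataset: LabeledDataset, fasta_path: str | Path, label_path: str | Path) -> None:
    """Write a generated dataset as FASTA plus the two-column label file."""
    write_fasta([(r.id, r.sequence) for r in dataset.records], fasta_path)
    write_label_table({r.id: r.label for r in dataset.records}, label_path)
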