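"""Amino-acid physicochemical scales and their PseAAC normalization.

Six scales are bundled with the package: hydrophobicity, hydrophilicity
(Hopp–Woods), side-chain mass, pK of the alpha-COOH group, pK of the
alpha-NH3+ group, and isoelectric point at 25 °C.  Before any correlation
factor is computed, each scale H0_k is converted to a dimensionless scale

    H_k(i) = (H0_k(i) - mean_20) / sqrt( sum_i (H0_k(i) - mean_20)^2 / 20 )

i.e. centred on the 20 standard residues and divided by the root-mean-square
deviation, so that every scale has mean 0 and RMS 1 and all scales enter the
sequence-order correlations on a commensurable footing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DegenerateScaleError, PropertyTableError

#: The 20 standard amino acids, in the fixed alphabetical one-letter order
#: used everywhere in this package (composition vector, property matrices).
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Canonical column order of the bundled scale file.
SCALE_NAMES: tuple[str, ...] = (
    "hydrophobicity",
    "hydrophilicity",
    "side_chain_mass",
    "pK_alpha_COOH",
    "pK_alpha_NH3",
    "pI_25C",
)

_RMS_TOL = 1e-12


def normalize_scale(raw) -> np.ndarray:
    """Normalize one 20-residue scale to mean 0, RMS 1.

    Parameters
    ----------
    raw : array-like of 20 floats
        Raw scale values in :data:`AMINO_ACIDS` order.

    Returns
    -------
    numpy.ndarray
        ``(raw - mean) / sqrt(mean((raw - mean)**2))``.

    Raises
    ------
    DegenerateScaleError
        If all 20 values are (numerically) equal, so the RMS deviation
        vanishes and the scale carries no information.
    """
    x = np.asarray(raw, dtype=float)
    if x.shape != (20,):
        raise PropertyTableError(f"expected 20 values per scale, got {x.shape}")
    dev = x - x.mean()
    rms = np.sqrt(np.mean(dev**2))
    scale = max(np.max(np.abs(x)), 1.0)
    if rms <= _RMS_TOL * scale:
        raise DegenerateScaleError("scale is constant across the 20 residues")
    return dev / rms


@dataclass(frozen=True)
class PropertyTable:
    """Raw and normalized values of the amino-acid property scales.

    Attributes
    ----------
    raw : pandas.DataFrame
        20 rows (index = one-letter residue codes in :data:`AMINO_ACIDS`
        order) by one column per scale; values exactly as read.
    normalized : pandas.DataFrame
        Same shape; each column centred and RMS-scaled per
        :func:`normalize_scale`.
    """

    raw: pd.DataFrame
    normalized: pd.DataFrame = field(repr=False)

    @property
    def scale_names(self) -> tuple[str, ...]:
        return tuple(self.raw.columns)

    def matrix(self, properties=None) -> np.ndarray:
        """Normalized values as an array of shape (n_properties, 20).

        ``properties`` is an ordered subset of scale names; ``None`` means
        all scales in table order. Column u corresponds to residue
        ``AMINO_ACIDS[u]``.
        """
        names = list(properties) if properties is not None else list(self.raw.columns)
        missing = [p for p in names if p not in self.normalized.columns]
        if missing:
            raise PropertyTableError(f"unknown scale(s): {missing}")
        return self.normalized[names].to_numpy().T.copy()


def load_property_table(source: str | Path | None = None) -> PropertyTable:
    """Load a scale table from a tab-separated file.

    The file has one row per amino acid (first column the one-letter code)
    and one column per scale. With ``source=None`` the six-scale table
    bundled with the package is loaded.

    Raises
    ------
    PropertyTableError
        Naming the (scale, residue) gap if any of the 20 standard residues
        or any expected scale is missing, or if a value is not numeric.
    """
    if source is None:
        with resources.as_file(
            resources.files("presep.data").joinpath("aa_scales.tsv")
        ) as p:
            df = pd.read_csv(p, sep="\t", comment="#", dtype={"aa": str})
        expected_scales = list(SCALE_NAMES)
    else:
        df = pd.read_csv(source, sep="\t", comment="#")
        expected_scales = [c for c in df.columns if c != "aa"]

    if "aa" not in df.columns:
        raise PropertyTableError("scale file must have an 'aa' column")
    df = df.set_index("aa")

    if not expected_scales:
        raise PropertyTableError("scale file defines no scales")
    for scale in expected_scales:
        if scale not in df.columns:
            raise PropertyTableError(f"missing scale column {scale!r}")
        for aa in AMINO_ACIDS:
            if aa not in df.index or pd.isna(df.at[aa, scale]):
                raise PropertyTableError(
                    f"missing value for ({scale!r}, {aa!r})"
                )
    extra = set(df.index) - set(AMINO_ACIDS)
    if extra:
        raise PropertyTableError(f"unexpected residue rows: {sorted(extra)}")

    raw = df.loc[list(AMINO_ACIDS), expected_scales].astype(float)
    normalized = raw.copy()
    for scale in expected_scales:
        normalized[scale] = normalize_scale(raw[scale].to_numpy())
    return PropertyTable(raw=raw, normalized=normalized)
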