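"""Independent naive PseAAC reference implementation.

Written straight from the defining formulas with plain Python loops and no
shared code with ``presep.pseaac`` (only the raw scale values are read from
the packaged TSV). Used as the oracle the vectorized encoder is checked
against; deliberately slow and literal.
"""

from __future__ import annotations

import csv
import math
from importlib import resources

AA = "ACDEFGHIKLMNPQRSTVWY"


def load_raw_scales() -> dict[str, dict[str, float]]:
    """{scale: {aa: raw value}} read directly from the packaged TSV."""
    with resources.files("presep.data").joinpath("aa_scales.tsv").open() as fh:
        rows = [r for r in csv.DictReader(fh, delimiter="\t") if not r["aa"].startswith("#")]
    scales: dict[str, dict[str, float]] = {}
    for row in rows:
        for key, val in row.items():
            if key == "aa":
                continue
            scales.setdefault(key, {})[row["aa"]] = float(val)
    return scales


def normalize(scale: dict[str, float]) -> dict[str, float]:
    mean = sum(scale[a] for a in AA) / 20.0
    rms = math.sqrt(sum((scale[a] - mean) ** 2 for a in AA) / 20.0)
    return {a: (scale[a] - mean) / rms for a in AA}


def naive_encode(
    seq: str,
    mode: str,
    w: float,
    lam: int,
    raw_scales: dict[str, dict[str, float]],
    properties: list[str],
) -> list[float]:
    """Literal double-loop PseAAC with the effective-lambda zero-padding rule."""
    H = {k: normalize(raw_scales[k]) for k in properties}
    L = len(seq)
    freqs = [seq.count(a) / L for a in AA]

    corr: list[float] = []
    if mode == "I":
        for j in range(1, lam + 1):
            if j > L - 1:
                corr.append(0.0)
                continue
            total = 0.0
            for i in range(L - j):
                theta_pair = 0.0
                for k in properties:
                    theta_pair += (H[k][seq[i + j]] - H[k][seq[i]]) ** 2
                total += theta_pair / len(properties)
            corr.append(total / (L - j))
    elif mode == "II":
        for j in range(1, lam + 1):
            for k in properties:
                if j > L - 1:
                    corr.append(0.0)
                    continue
                total = 0.0
                for i in range(L - j):
                    total += H[k][seq[i]] * H[k][seq[i + j]]
                corr.append(total / (L - j))
    else:
        raise ValueError(mode)

    denom = sum(freqs) + w * sum(corr)
    return [f / denom for f in freqs] + [w * c / denom for c in corr]
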