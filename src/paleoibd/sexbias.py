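"""Sex-biased admixture Z statistic from autosomal vs X-chromosome ancestry.

z = (P_A - P_X) / sqrt(sigma_A^2 + sigma_X^2). Positive z means the
ancestry is overrepresented on autosomes relative to the X chromosome,
i.e. a male-biased contribution of that ancestry; negative z means a
female-biased contribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import sqrt
from pathlib import Path

import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class AncestryEstimate:
    source: str
    P_A: float
    sigma_A: float
    P_X: float
    sigma_X: float
    target: str = ""

    def __post_init__(self) -> None:
        if self.sigma_A <= 0 or self.sigma_X <= 0:
            raise ValueError(
                f"standard errors must be positive, got {self.sigma_A}, {self.sigma_X}"
            )
        for name, p in (("P_A", self.P_A), ("P_X", self.P_X)):
            if not 0.0 <= p <= 1.0:
                warnings.warn(
                    f"{name}={p} outside [0, 1] for {self.source}: "
                    "out-of-range fit output admitted",
                    stacklevel=2,
                )


def sexbias_z(est: AncestryEstimate) -> float:
    """Z score for sex-biased admixture of one ancestry source."""
    return (est.P_A - est.P_X) / sqrt(est.sigma_A**2 + est.sigma_X**2)


def sexbias_table(path_in: str | Path, path_out: str | Path | None = None) -> pd.DataFrame:
    """Annotate a `target source P_A sigma_A P_X sigma_X` TSV with z and p.

    The two-sided normal p-value is a reporting aid only.
    """
    df = pd.read_csv(path_in, sep="\t")
    required = ["target", "source", "P_A", "sigma_A", "P_X", "sigma_X"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"ancestry table {path_in} is missing column {col!r}")
    zs = [
        sexbias_z(
            AncestryEstimate(
                source=row.source,
                P_A=row.P_A,
                sigma_A=row.sigma_A,
                P_X=row.P_X,
                sigma_X=row.sigma_X,
                target=row.target,
            )
        )
        for row in df.itertuples(index=False)
    ]
    df = df.copy()
    df["z"] = zs
    df["p_normal_two_sided"] = [2 * stats.norm.sf(abs(z)) for z in zs]
    if path_out is not None:
        df.to_csv(path_out, sep="\t", index=False)
    return df
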