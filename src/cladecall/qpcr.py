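"""Relative quantification of qRT-PCR Ct tables.

The quantity of interest is the log2 expression ratio of a panel gene in an
evolved clone over the ancestor, internally normalized to the *ACT1*
reference.  With per-primer amplification efficiencies ``E`` the
efficiency-corrected (Pfaffl-style) ratio is

    ratio = (1 + E_ref)^dCt_ref / (1 + E_gene)^dCt_gene,

``dCt_x = Ct_x(clone) - Ct_x(ancestor)``, so on the log2 scale

    log2_ratio = dCt_ref * log2(1 + E_ref) - dCt_gene * log2(1 + E_gene).

Setting every efficiency to 1 recovers the classical 2^-ddCt model.

Replicate handling: technical replicates are averaged first; the ratio is
computed per biological replicate (clone bio-replicate b against ancestor
bio-replicate b, falling back to the pooled ancestor mean when the ancestor
lacks that replicate), and the reported value is the mean over biological
replicates with its standard error (``mode="bio_sem"``, default).  The
alternative ``mode="quadrature"`` propagates the four per-term Ct standard
errors in quadrature instead.  When a ``batch`` column is present, clones
are normalized against the ancestor rows of the same batch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from cladecall.errors import ConfigurationError, DegenerateDataError, MissingDataError
from cladecall.signatures import DEFAULT_PANEL, REFERENCE_GENE
from cladecall.simulate import DEFAULT_EFFICIENCIES


@dataclass(frozen=True)
class StandardCurve:
    """Dilution-series calibration of one primer pair.

    ``slope`` is cycles per log10(dilution); a valid curve has negative
    slope and ``efficiency = 10**(-1/slope) - 1`` (1.0 for perfect
    doubling).  ``linear_range`` is the widest contiguous dilution window
    whose own fit reaches the r² threshold.
    """

    primer_pair: str
    slope: float
    intercept: float
    efficiency: float
    r_squared: float
    linear_range: tuple[float, float]
    valid: bool = True
    message: str = ""


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least squares y = a*x + b; returns (a, b, r_squared)."""
    a, b = np.polyfit(x, y, 1)
    fitted = a * x + b
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(a), float(b), r2


def fit_standard_curve(
    dilutions: Sequence[float],
    ct_values: Sequence[float],
    primer_pair: str = "",
    r2_threshold: float = 0.99,
) -> StandardCurve:
    """Fit Ct against log10(dilution) by ordinary least squares.

    Requires at least three distinct dilutions.  A non-negative slope yields
    a flagged invalid curve (``valid=False``) rather than an exception, so
    callers can surface the warning alongside other primers.
    """
    dil = np.asarray(dilutions, dtype=float)
    ct = np.asarray(ct_values, dtype=float)
    if dil.shape != ct.shape:
        raise ConfigurationError("dilutions and ct_values must align")
    if np.any(dil <= 0):
        raise ConfigurationError("dilutions must be positive fractions")
    distinct = np.unique(dil)
    if distinct.size < 3:
        raise DegenerateDataError(
            f"standard curve for {primer_pair or 'primer'} needs >=3 distinct "
            f"dilutions, got {distinct.size}"
        )
    x = np.log10(dil)
    slope, intercept, r2 = _ols(x, ct)
    if slope >= 0:
        return StandardCurve(
            primer_pair, slope, intercept, float("nan"), r2,
            (float(distinct.min()), float(distinct.max())),
            valid=False,
            message="non-negative slope: Ct does not increase with dilution",
        )
    efficiency = 10.0 ** (-1.0 / slope) - 1.0

    # widest contiguous dilution window whose own OLS reaches the threshold
    best = (float(distinct.min()), float(distinct.max()))
    best_span = -1
    order = np.argsort(distinct)
    levels = distinct[order]
    for i in range(len(levels)):
        for j in range(i + 2, len(levels)):
            mask = (dil >= levels[i]) & (dil <= levels[j])
            _, _, r2w = _ols(np.log10(dil[mask]), ct[mask])
            if r2w >= r2_threshold and (j - i) > best_span:
                best_span = j - i
                best = (float(levels[i]), float(levels[j]))
    return StandardCurve(
        primer_pair, slope, intercept, float(efficiency), r2, best, valid=True
    )


def fit_standard_curves(
    table: pd.DataFrame, r2_threshold: float = 0.99
) -> dict[str, StandardCurve]:
    """Fit one curve per primer pair from a tidy `primer_pair dilution ct` table."""
    out = {}
    for primer, sub in table.groupby("primer_pair", sort=True):
        out[str(primer)] = fit_standard_curve(
            sub["dilution"].to_numpy(), sub["ct"].to_numpy(),
            primer_pair=str(primer), r2_threshold=r2_threshold,
        )
    return out


def _bio_means(
    ct: pd.DataFrame, clone: str, gene: str
) -> pd.Series:
    """Mean Ct over technical replicates, indexed by bio_rep."""
    sub = ct[(ct["clone"] == clone) & (ct["gene"] == gene)]
    if sub.empty:
        raise MissingDataError(f"no Ct measurements for clone {clone!r}, gene {gene!r}")
    return sub.groupby("bio_rep")["ct"].mean()


def _split_batches(
    ct: pd.DataFrame, clone: str, ancestor: str
) -> list[pd.DataFrame]:
    """Return per-batch sub-tables pairing the clone with its batch ancestor."""
    if "batch" not in ct.columns:
        return [ct]
    batches = sorted(ct.loc[ct["clone"] == clone, "batch"].unique())
    out = []
    for b in batches:
        sub = ct[ct["batch"] == b]
        if (sub["clone"] == ancestor).any():
            out.append(sub)
        else:  # fall back to the pooled ancestor across batches
            out.append(
                pd.concat([sub, ct[ct["clone"] == ancestor]], ignore_index=True)
            )
    return out


def relative_expression(
    ct: pd.DataFrame,
    clone: str,
    ancestor: str,
    gene: str,
    reference_gene: str = REFERENCE_GENE,
    efficiencies: Mapping[str, float] | None = None,
    mode: str = "bio_sem",
) -> tuple[float, float]:
    """Ancestor-relative, reference-normalized log2 expression ratio.

    Returns ``(log2_ratio, se)``.  ``mode="bio_sem"`` (default) reports the
    SEM of the per-biological-replicate log2 ratios; ``mode="quadrature"``
    propagates the per-term Ct SEMs in quadrature.  With a single biological
    replicate the bio-SEM is undefined and reported as 0.0.
    """
    if mode not in ("bio_sem", "quadrature"):
        raise ConfigurationError(f"unknown error mode {mode!r}")
    eff = dict(DEFAULT_EFFICIENCIES if efficiencies is None else efficiencies)
    for g in (gene, reference_gene):
        if g not in eff:
            raise ConfigurationError(f"no amplification efficiency for gene {g!r}")
    w_gene = math.log2(1.0 + eff[gene])
    w_ref = math.log2(1.0 + eff[reference_gene])

    ratios: list[float] = []
    var_terms: list[float] = []
    for sub in _split_batches(ct, clone, ancestor):
        cg = _bio_means(sub, clone, gene)
        cr = _bio_means(sub, clone, reference_gene)
        ag = _bio_means(sub, ancestor, gene)
        ar = _bio_means(sub, ancestor, reference_gene)
        for b in cg.index:
            if b not in cr.index:
                raise MissingDataError(
                    f"clone {clone!r} bio replicate {b}: gene {gene!r} measured "
                    f"but reference {reference_gene!r} missing"
                )
            anc_g = ag[b] if b in ag.index else ag.mean()
            anc_r = ar[b] if b in ar.index else ar.mean()
            d_gene = cg[b] - anc_g
            d_ref = cr[b] - anc_r
            ratios.append(d_ref * w_ref - d_gene * w_gene)
        if mode == "quadrature":
            for series, w in ((cg, w_gene), (cr, w_ref), (ag, w_gene), (ar, w_ref)):
                n = len(series)
                v = float(series.var(ddof=1)) / n if n > 1 else 0.0
                var_terms.append(v * w * w)

    arr = np.asarray(ratios, dtype=float)
    log2_ratio = float(arr.mean())
    if mode == "bio_sem":
        se = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
    else:
        se = math.sqrt(sum(var_terms))
    return log2_ratio, se


@dataclass
class ExpressionMatrix:
    """Clones x panel-genes matrix of log2 ratios with a parallel SE matrix."""

    log2: pd.DataFrame
    se: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.log2.index.equals(self.se.index) or not self.log2.columns.equals(
            self.se.columns
        ):
            raise ConfigurationError("log2 and se matrices must share labels")
        if self.log2.index.has_duplicates or self.log2.columns.has_duplicates:
            raise ConfigurationError("clone and gene labels must be unique")
        if not np.isfinite(self.log2.to_numpy()).all():
            raise ConfigurationError("expression matrix contains non-finite values")

    @property
    def clones(self) -> list[str]:
        return list(self.log2.index)

    @property
    def genes(self) -> list[str]:
        return list(self.log2.columns)

    def values(self) -> np.ndarray:
        return self.log2.to_numpy(dtype=float)


def build_matrix(
    ct: pd.DataFrame,
    ancestor: str,
    panel: Sequence[str] = DEFAULT_PANEL,
    reference_gene: str = REFERENCE_GENE,
    efficiencies: Mapping[str, float] | None = None,
    mode: str = "bio_sem",
    clones: Iterable[str] | None = None,
) -> ExpressionMatrix:
    """Quantify every clone on the full panel.

    Row order follows first appearance in the Ct table (the ancestor is
    excluded); column order follows ``panel``.  Any clone missing any panel
    gene aborts with a single error listing every gap.
    """
    if clones is None:
        clone_list = [
            c for c in pd.unique(ct["clone"]) if c != ancestor
        ]
    else:
        clone_list = list(clones)
    if not (ct["clone"] == ancestor).any():
        raise MissingDataError(f"ancestor {ancestor!r} absent from Ct table")

    gaps = []
    present = ct.groupby("clone")["gene"].agg(set)
    needed = set(panel) | {reference_gene}
    for c in clone_list:
        have = present.get(c, set())
        for g in sorted(needed - set(have)):
            gaps.append(f"{c}:{g}")
    if gaps:
        raise MissingDataError(
            "missing panel measurements for " + ", ".join(gaps)
        )

    vals = np.empty((len(clone_list), len(panel)))
    ses = np.empty_like(vals)
    for i, c in enumerate(clone_list):
        for j, g in enumerate(panel):
            vals[i, j], ses[i, j] = relative_expression(
                ct, c, ancestor, g, reference_gene, efficiencies, mode
            )
    idx = pd.Index(clone_list, name="clone")
    cols = pd.Index(list(panel), name="gene")
    return ExpressionMatrix(
        pd.DataFrame(vals, index=idx, columns=cols),
        pd.DataFrame(ses, index=idx, columns=cols),
    )
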