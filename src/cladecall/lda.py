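"""Fisher linear discriminant analysis of expression profiles.

Fisher's construction is specified explicitly so results are
implementation-independent: with between-class scatter ``Sb`` and pooled
within-class scatter ``Sw``, the discriminant axes solve the generalized
eigenproblem ``Sb w = lambda Sw w`` and are ordered by decreasing
eigenvalue; at most ``min(genes, classes - 1)`` axes are informative.
``Sw`` is ridge-regularized with ``lambda * trace(Sw)/p * I`` (falling back
to ``lambda * I`` when the trace vanishes) to tolerate small classes on a
five-gene panel.

Classification uses the Gaussian model with the pooled covariance
``Sw / (n - K)`` and class-proportional priors (uniform optionally);
cross-validation is leave-one-out.  Confidence ellipses on the first two
discriminant scores use the chi-square (known-covariance) scaling
``sqrt(chi2.ppf(level, 2))``; the F-based (Hotelling) small-sample scaling
is available via a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from cladecall.errors import ConfigurationError, DegenerateDataError
from cladecall.qpcr import ExpressionMatrix


@dataclass(frozen=True)
class ConfidenceEllipse:
    """Confidence ellipse in 2-D score space."""

    class_name: str
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle: float  # radians, orientation of the first semi-axis
    level: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside (or on) the ellipse."""
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(self.center)
        c, s = math.cos(self.angle), math.sin(self.angle)
        rot = np.array([[c, s], [-s, c]])
        uv = pts @ rot.T
        a, b = self.semi_axes
        return (uv[:, 0] / a) ** 2 + (uv[:, 1] / b) ** 2 <= 1.0 + 1e-12

    def bounding_box(self) -> tuple[float, float, float, float]:
        a, b = self.semi_axes
        c, s = math.cos(self.angle), math.sin(self.angle)
        dx = math.hypot(a * c, b * s)
        dy = math.hypot(a * s, b * c)
        x0, y0 = self.center
        return (x0 - dx, x0 + dx, y0 - dy, y0 + dy)


def ellipse_from_moments(
    mean: Sequence[float],
    cov: np.ndarray,
    level: float = 0.95,
    class_name: str = "",
    scaling: str = "chi2",
    n: int | None = None,
) -> ConfidenceEllipse:
    """Ellipse of a 2-D Gaussian at the given coverage level.

    ``scaling="chi2"`` uses the known-covariance radius
    ``sqrt(chi2.ppf(level, 2))``; ``scaling="f"`` uses the Hotelling
    small-sample radius and requires ``n``.
    """
    if not (0.0 < level < 1.0):
        raise ConfigurationError("level must be in (0, 1)")
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (2, 2):
        raise ConfigurationError("covariance must be 2x2")
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 0 or not np.isfinite(evals).all():
        raise DegenerateDataError("singular covariance: no ellipse")
    if scaling == "chi2":
        r2 = stats.chi2.ppf(level, df=2)
    elif scaling == "f":
        if n is None or n < 3:
            raise ConfigurationError("F-based scaling needs the sample size n >= 3")
        r2 = 2 * (n - 1) / (n - 2) * stats.f.ppf(level, 2, n - 2)
    else:
        raise ConfigurationError(f"unknown scaling {scaling!r}")
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    semi = tuple(float(math.sqrt(v * r2)) for v in evals)
    angle = float(math.atan2(evecs[1, 0], evecs[0, 0]))
    return ConfidenceEllipse(class_name, (float(mean[0]), float(mean[1])), semi, angle, level)


def confidence_ellipse(
    points: np.ndarray,
    level: float = 0.95,
    class_name: str = "",
    scaling: str = "chi2",
) -> ConfidenceEllipse:
    """Confidence ellipse from the sample mean and covariance of 2-D scores."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ConfigurationError("points must be an (n, 2) array")
    if pts.shape[0] < 3:
        raise DegenerateDataError(
            f"confidence ellipse needs >= 3 points, got {pts.shape[0]}"
        )
    mean = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    return ellipse_from_moments(
        mean, cov, level, class_name, scaling, n=pts.shape[0]
    )


def ellipse_overlap(
    e1: ConfidenceEllipse, e2: ConfidenceEllipse, grid: int = 400
) -> float:
    """Area of intersection of two ellipses by grid integration."""
    b1, b2 = e1.bounding_box(), e2.bounding_box()
    x0, x1 = max(b1[0], b2[0]), min(b1[1], b2[1])
    y0, y1 = max(b1[2], b2[2]), min(b1[3], b2[3])
    if x0 >= x1 or y0 >= y1:
        return 0.0
    xs = np.linspace(x0, x1, grid)
    ys = np.linspace(y0, y1, grid)
    xx, yy = np.meshgrid(xs, ys)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    inside = e1.contains(pts) & e2.contains(pts)
    cell = (xs[1] - xs[0]) * (ys[1] - ys[0])
    return float(inside.sum() * cell)


class LinearDiscriminant:
    """Fisher LDA model over an expression matrix and a class grouping.

    Parameters
    ----------
    matrix
        :class:`~cladecall.qpcr.ExpressionMatrix` or clones x genes frame.
    grouping
        Mapping or Series from clone id to class (adaptive mutation or
        ploidy); every clone in the matrix must be covered.
    reg
        Ridge coefficient for the within-class scatter.
    priors
        ``"proportional"`` (default) or ``"uniform"``.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix | pd.DataFrame,
        grouping: Mapping[str, str] | pd.Series,
        reg: float = 1e-6,
        priors: str = "proportional",
    ) -> None:
        self.frame = matrix.log2 if isinstance(matrix, ExpressionMatrix) else matrix
        grouping = dict(grouping)
        missing = [c for c in self.frame.index if c not in grouping]
        if missing:
            raise ConfigurationError(f"no class for clones: {missing}")
        if priors not in ("proportional", "uniform"):
            raise ConfigurationError(f"unknown priors {priors!r}")
        self.groups = pd.Series(
            [grouping[c] for c in self.frame.index], index=self.frame.index
        )
        self.reg = float(reg)
        self.priors = priors
        counts = self.groups.value_counts()
        if len(counts) < 2:
            raise ConfigurationError("need at least two classes")
        singletons = sorted(counts.index[counts < 2])
        if singletons:
            raise ConfigurationError(
                f"classes with a single member cannot be fit: {singletons}"
            )

    # --- Fisher construction -------------------------------------------------

    @staticmethod
    def _scatter(
        x: np.ndarray, y: np.ndarray, classes: Sequence[str]
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return (Sw, Sb, class means, grand mean)."""
        p = x.shape[1]
        grand = x.mean(axis=0)
        sw = np.zeros((p, p))
        sb = np.zeros((p, p))
        means = np.empty((len(classes), p))
        for k, cls in enumerate(classes):
            xk = x[y == cls]
            mk = xk.mean(axis=0)
            means[k] = mk
            centered = xk - mk
            sw += centered.T @ centered
            d = (mk - grand)[:, None]
            sb += xk.shape[0] * (d @ d.T)
        return sw, sb, means, grand

    def fit(self) -> "LdaResults":
        x = self.frame.to_numpy(dtype=float)
        y = self.groups.to_numpy()
        classes = sorted(pd.unique(y))
        sw, sb, means, grand = self._scatter(x, y, classes)

        p = x.shape[1]
        tr = np.trace(sw)
        sw_reg = sw + self.reg * (tr / p if tr > 0 else 1.0) * np.eye(p)
        evals, evecs = linalg.eigh(sb, sw_reg)
        order = np.argsort(evals)[::-1]
        n_axes = min(p, len(classes) - 1)
        evals = np.maximum(evals[order][:n_axes], 0.0)
        axes = evecs[:, order][:, :n_axes]
        # sign convention: largest-magnitude loading positive
        for j in range(axes.shape[1]):
            i = int(np.argmax(np.abs(axes[:, j])))
            if axes[i, j] < 0:
                axes[:, j] = -axes[:, j]

        degenerate = bool(evals.size == 0 or evals[0] <= 1e-12)
        scores = (x - grand) @ axes
        score_cols = [f"ld{j + 1}" for j in range(axes.shape[1])]
        return LdaResults(
            model=self,
            classes=tuple(classes),
            class_means=pd.DataFrame(means, index=classes, columns=self.frame.columns),
            grand_mean=grand,
            within_scatter=sw,
            axes=pd.DataFrame(axes, index=self.frame.columns, columns=score_cols),
            eigenvalues=evals,
            scores=pd.DataFrame(scores, index=self.frame.index, columns=score_cols),
            degenerate=degenerate,
        )


@dataclass
class LdaResults:
    """Fitted Fisher discriminant: axes, scores, and classification tools."""

    model: LinearDiscriminant
    classes: tuple[str, ...]
    class_means: pd.DataFrame
    grand_mean: np.ndarray
    within_scatter: np.ndarray
    axes: pd.DataFrame
    eigenvalues: np.ndarray
    scores: pd.DataFrame
    degenerate: bool = False

    def _pooled_cov_inv(self) -> np.ndarray:
        n = self.model.frame.shape[0]
        k = len(self.classes)
        p = self.within_scatter.shape[0]
        cov = self.within_scatter / max(n - k, 1)
        tr = np.trace(cov)
        cov = cov + self.model.reg * (tr / p if tr > 0 else 1.0) * np.eye(p)
        return np.linalg.inv(cov)

    def _log_priors(self) -> np.ndarray:
        if self.model.priors == "uniform":
            return np.zeros(len(self.classes))
        counts = self.model.groups.value_counts()
        n = counts.sum()
        return np.log(
            np.array([counts[c] / n for c in self.classes], dtype=float)
        )

    def classify(self, x: np.ndarray | pd.DataFrame) -> np.ndarray:
        """Gaussian LDA rule with pooled covariance and configured priors."""
        arr = np.atleast_2d(np.asarray(x, dtype=float))
        cov_inv = self._pooled_cov_inv()
        mu = self.class_means.to_numpy()
        lp = self._log_priors()
        disc = arr @ cov_inv @ mu.T - 0.5 * np.einsum(
            "ij,jk,ik->i", mu, cov_inv, mu
        ) + lp
        return np.array([self.classes[i] for i in disc.argmax(axis=1)])

    def training_accuracy(self) -> float:
        pred = self.classify(self.model.frame.to_numpy())
        return float((pred == self.model.groups.to_numpy()).mean())

    def loocv(self) -> dict:
        """Leave-one-out cross-validated accuracy (overall and per class)."""
        frame = self.model.frame
        groups = self.model.groups
        hits: dict[str, list[bool]] = {c: [] for c in self.classes}
        for clone in frame.index:
            rest = frame.drop(index=clone)
            rest_groups = groups.drop(index=clone)
            if rest_groups.value_counts().min() < 2:
                # leaving this clone out would strand a singleton class
                continue
            sub = LinearDiscriminant(
                rest, rest_groups, reg=self.model.reg, priors=self.model.priors
            ).fit()
            pred = sub.classify(frame.loc[[clone]].to_numpy())[0]
            hits.setdefault(groups[clone], []).append(pred == groups[clone])
        per_class = {
            c: float(np.mean(v)) for c, v in hits.items() if v
        }
        all_hits = [h for v in hits.values() for h in v]
        return {
            "n": len(all_hits),
            "accuracy": float(np.mean(all_hits)) if all_hits else float("nan"),
            "per_class_accuracy": per_class,
        }

    def ellipse(
        self, class_name: str, level: float = 0.95, scaling: str = "chi2"
    ) -> ConfidenceEllipse:
        """Confidence ellipse of one class on the first two discriminant axes."""
        mask = self.model.groups == class_name
        pts = self.scores.loc[mask].iloc[:, :2].to_numpy()
        return confidence_ellipse(pts, level, class_name, scaling)

    def ellipses(self, level: float = 0.95) -> dict[str, ConfidenceEllipse]:
        out = {}
        for c in self.classes:
            if int((self.model.groups == c).sum()) >= 3:
                out[c] = self.ellipse(c, level)
        return out

    def summary(self) -> str:
        ev = self.eigenvalues
        frac = ev / ev.sum() if ev.sum() > 0 else ev
        lines = [
            f"Fisher linear discriminant analysis ({len(self.classes)} classes, "
            f"{self.model.frame.shape[0]} clones, {self.model.frame.shape[1]} genes)",
            "  classes: " + ", ".join(self.classes),
        ]
        if self.degenerate:
            lines.append("  DEGENERATE: no discriminative axis (classes identical)")
        for j, (e, f) in enumerate(zip(ev, frac)):
            lines.append(f"  LD{j + 1}: eigenvalue {e:.4g} ({100 * f:.1f}% of trace)")
        lines.append(f"  training accuracy: {self.training_accuracy():.3f}")
        return "\n".join(lines)

    def plot(self, ax=None, level: float = 0.95):
        """Scatter of the first two discriminant scores with class ellipses."""
        import matplotlib.pyplot as plt
        from matplotlib.patches import Ellipse as MplEllipse

        if ax is None:
            _, ax = plt.subplots()
        for c in self.classes:
            pts = self.scores.loc[self.model.groups == c].iloc[:, :2]
            ax.scatter(pts.iloc[:, 0], pts.iloc[:, 1], label=c, s=18)
        for c, e in self.ellipses(level).items():
            ax.add_patch(
                MplEllipse(
                    e.center,
                    2 * e.semi_axes[0],
                    2 * e.semi_axes[1],
                    angle=math.degrees(e.angle),
                    fill=False,
                )
            )
        ax.set_xlabel("LD1")
        ax.set_ylabel("LD2")
        ax.legend(fontsize=7)
        return ax


def separation_report(
    results_by_mutation: LdaResults,
    results_by_ploidy: LdaResults,
    level: float = 0.95,
) -> dict:
    """Compare how well the two groupings separate the same clones.

    Reports LOOCV accuracy per grouping, pairwise confidence-ellipse overlap
    areas, and a flag set when every mutation-class accuracy exceeds every
    ploidy-class accuracy.
    """
    a, b = results_by_mutation, results_by_ploidy
    if not a.model.frame.index.equals(b.model.frame.index):
        raise ConfigurationError("the two models must be fit on the same clones")

    def overlaps(res: LdaResults) -> dict[tuple[str, str], float]:
        es = res.ellipses(level)
        names = sorted(es)
        return {
            (x, y): ellipse_overlap(es[x], es[y])
            for i, x in enumerate(names)
            for y in names[i + 1 :]
        }

    cv_mut = a.loocv()
    cv_plo = b.loocv()
    mut_acc = cv_mut["per_class_accuracy"].values()
    plo_acc = cv_plo["per_class_accuracy"].values()
    flag = bool(mut_acc and plo_acc and min(mut_acc) > max(plo_acc))
    return {
        "by_mutation": {"loocv": cv_mut, "ellipse_overlap": overlaps(a)},
        "by_ploidy": {"loocv": cv_plo, "ellipse_overlap": overlaps(b)},
        "mutation_separates_better": flag,
    }
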