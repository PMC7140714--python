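"""Differential expression calling by per-gene three-way ANOVA.

Each gene's log2 expression is modelled with a fixed-effects factorial ANOVA
over genotype x sulfur condition x tissue (main effects plus all
interactions), fitted by ordinary least squares on a balanced design. A gene
is a DEG for one contrast (genotype, tissue) when the linear-scale fold
change of the stressed vs reference condition reaches ±``fc_threshold`` and
the contrast p-value is below ``alpha`` — the classic "FC >= ±1.5 and
p < 0.05" filter.

The model/results pair follows the statsmodels idiom:

    res = FactorialAnova(study).fit()
    res.summary()          # per-term F and p for the first genes
    sets = res.call_degs() # direction-labelled DEG sets per contrast

Because the design is balanced and the model saturated, fitted cell means
are sample cell means and the residual variance is the pooled within-cell
variance; the condition contrast within a (genotype, tissue) cell pair is a
two-mean linear contrast with the pooled error, which is exactly the OLS
linear-contrast test under the full model.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionStudy",
    "DegRecord",
    "DegSet",
    "FactorialAnova",
    "FactorialAnovaResults",
    "fit_anova_per_gene",
    "call_degs",
    "contrast_label",
    "signed_fold_change",
]

FACTORS = ("genotype", "condition", "tissue")
TERMS = (
    "genotype",
    "condition",
    "tissue",
    "genotype:condition",
    "genotype:tissue",
    "condition:tissue",
    "genotype:condition:tissue",
)


class DegenerateDesignError(ValueError):
    """A factor has fewer than two levels, or the design is not balanced."""


def contrast_label(genotype: str, tissue: str) -> str:
    return f"{genotype}:{tissue}"


def signed_fold_change(log2_diff: float | np.ndarray) -> np.ndarray:
    """Linear fold change sign-coded as in the ±1.5 convention.

    2**d when d >= 0, else -2**(-d); magnitude is always >= 1.
    """
    d = np.asarray(log2_diff, dtype=float)
    return np.where(d >= 0, np.exp2(d), -np.exp2(-d))


@dataclass
class ExpressionStudy:
    """Normalized log2 expression matrix plus per-sample factor labels.

    ``matrix`` is genes x samples; ``samples`` is indexed by sample id with
    columns genotype, condition, tissue, replicate. ``condition_levels``
    orders the sulfur factor (reference first, stressed second) so the
    contrast direction is unambiguous.
    """

    matrix: pd.DataFrame
    samples: pd.DataFrame
    condition_levels: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        missing = [c for c in FACTORS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample table lacks factor column(s): {missing}")
        if not self.matrix.columns.equals(self.samples.index):
            # allow same labels in different order
            if set(self.matrix.columns) != set(self.samples.index):
                raise ValueError("matrix columns and sample table disagree")
            self.samples = self.samples.loc[self.matrix.columns]
        if self.condition_levels is None:
            seen = list(dict.fromkeys(self.samples["condition"]))
            if len(seen) != 2:
                raise DegenerateDesignError(
                    f"condition must have exactly 2 levels, found {seen}"
                )
            self.condition_levels = (seen[0], seen[1])
        n_bad = int(self.matrix.isna().any(axis=1).sum())
        if n_bad:
            logger.info("dropping %d gene rows with missing values", n_bad)
            self.matrix = self.matrix.dropna(axis=0)

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    def factor_levels(self, factor: str) -> list[str]:
        if factor == "condition" and self.condition_levels is not None:
            return list(self.condition_levels)
        return list(dict.fromkeys(self.samples[factor]))

    def contrasts(self) -> list[tuple[str, str]]:
        return list(
            itertools.product(
                self.factor_levels("genotype"), self.factor_levels("tissue")
            )
        )


@dataclass(frozen=True)
class DegRecord:
    gene_id: str
    contrast: str
    fold_change: float  # signed linear scale
    p_value: float
    direction: str  # up | down | unchanged


@dataclass
class DegSet:
    contrast: str
    direction: str
    gene_ids: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.gene_ids)


def _balanced_cube(study: ExpressionStudy):
    """Reshape the matrix into (genes, a, b, k, n) over the factor grid."""
    g_levels = study.factor_levels("genotype")
    c_levels = study.factor_levels("condition")
    t_levels = study.factor_levels("tissue")
    for name, lv in (("genotype", g_levels), ("condition", c_levels),
                     ("tissue", t_levels)):
        if len(lv) < 2:
            raise DegenerateDesignError(f"factor {name!r} has a single level")
    gi = study.samples["genotype"].map({v: i for i, v in enumerate(g_levels)})
    ci = study.samples["condition"].map({v: i for i, v in enumerate(c_levels)})
    ti = study.samples["tissue"].map({v: i for i, v in enumerate(t_levels)})
    counts = pd.crosstab([gi, ci], ti).to_numpy()
    n_rep = counts.flat[0]
    if counts.size != len(g_levels) * len(c_levels) * len(t_levels) or not (
        counts == n_rep
    ).all():
        raise DegenerateDesignError("design is not balanced across all cells")
    if n_rep < 2:
        raise DegenerateDesignError("each design cell needs >= 2 replicates")
    a, b, k = len(g_levels), len(c_levels), len(t_levels)
    cube = np.empty((study.matrix.shape[0], a, b, k, n_rep))
    slot = np.zeros((a, b, k), dtype=int)
    vals = study.matrix.to_numpy()
    for j, (ia, ib, ik) in enumerate(zip(gi, ci, ti)):
        cube[:, ia, ib, ik, slot[ia, ib, ik]] = vals[:, j]
        slot[ia, ib, ik] += 1
    return cube, (g_levels, c_levels, t_levels)


def _term_ss(cube: np.ndarray) -> tuple[dict[str, np.ndarray], dict[str, int],
                                        np.ndarray, int]:
    """Classical balanced three-way ANOVA sums of squares, vectorised.

    Returns per-term SS, per-term df, residual SS, residual df.
    """
    n_genes, a, b, k, n = cube.shape
    grand = cube.mean(axis=(1, 2, 3, 4))
    m_a = cube.mean(axis=(2, 3, 4))  # (genes, a)
    m_b = cube.mean(axis=(1, 3, 4))
    m_c = cube.mean(axis=(1, 2, 4))
    m_ab = cube.mean(axis=(3, 4))  # (genes, a, b)
    m_ac = cube.mean(axis=(2, 4))
    m_bc = cube.mean(axis=(1, 4))
    m_abc = cube.mean(axis=4)

    g = grand[:, None]
    ss = {
        "genotype": b * k * n * ((m_a - g) ** 2).sum(axis=1),
        "condition": a * k * n * ((m_b - g) ** 2).sum(axis=1),
        "tissue": a * b * n * ((m_c - g) ** 2).sum(axis=1),
    }
    g2 = grand[:, None, None]
    ss["genotype:condition"] = k * n * (
        (m_ab - m_a[:, :, None] - m_b[:, None, :] + g2) ** 2
    ).sum(axis=(1, 2))
    ss["genotype:tissue"] = b * n * (
        (m_ac - m_a[:, :, None] - m_c[:, None, :] + g2) ** 2
    ).sum(axis=(1, 2))
    ss["condition:tissue"] = a * n * (
        (m_bc - m_b[:, :, None] - m_c[:, None, :] + g2) ** 2
    ).sum(axis=(1, 2))
    g3 = grand[:, None, None, None]
    ss["genotype:condition:tissue"] = n * (
        (
            m_abc
            - m_ab[:, :, :, None]
            - m_ac[:, :, None, :]
            - m_bc[:, None, :, :]
            + m_a[:, :, None, None]
            + m_b[:, None, :, None]
            + m_c[:, None, None, :]
            - g3
        )
        ** 2
    ).sum(axis=(1, 2, 3))
    df = {
        "genotype": a - 1,
        "condition": b - 1,
        "tissue": k - 1,
        "genotype:condition": (a - 1) * (b - 1),
        "genotype:tissue": (a - 1) * (k - 1),
        "condition:tissue": (b - 1) * (k - 1),
        "genotype:condition:tissue": (a - 1) * (b - 1) * (k - 1),
    }
    ss_resid = ((cube - m_abc[..., None]) ** 2).sum(axis=(1, 2, 3, 4))
    df_resid = a * b * k * (n - 1)
    return ss, df, ss_resid, df_resid


def _p_from_f(ss_term, df_term, ss_resid, df_resid):
    """F-test p-values with zero-variance conventions.

    Residual SS of zero: a non-zero effect is a perfect separation (p -> 0),
    a zero effect is a constant gene reported as no-effect (p = 1).
    """
    tol = 1e-12
    ms_resid = ss_resid / df_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_term / df_term) / ms_resid
        p = stats.f.sf(f, df_term, df_resid)
    degenerate = ss_resid <= tol
    p = np.where(degenerate & (ss_term <= tol), 1.0, p)
    p = np.where(degenerate & (ss_term > tol), 0.0, p)
    f = np.where(degenerate, np.inf, f)
    f = np.where(degenerate & (ss_term <= tol), 0.0, f)
    return f, p


class FactorialAnova:
    """Per-gene three-way fixed-effects ANOVA model for an expression study."""

    def __init__(self, study: ExpressionStudy):
        self.study = study

    def fit(self) -> "FactorialAnovaResults":
        cube, levels = _balanced_cube(self.study)
        ss, df, ss_resid, df_resid = _term_ss(cube)
        genes = self.study.genes
        f_frame = pd.DataFrame(index=genes)
        p_frame = pd.DataFrame(index=genes)
        for term in TERMS:
            f, p = _p_from_f(ss[term], df[term], ss_resid, df_resid)
            f_frame[term] = f
            p_frame[term] = p

        # Condition contrast (stressed - reference) per genotype x tissue,
        # tested against the pooled residual variance.
        g_levels, c_levels, t_levels = levels
        n = cube.shape[4]
        s2 = ss_resid / df_resid
        rows = []
        tol = 1e-12
        for ia, geno in enumerate(g_levels):
            for ik, tis in enumerate(t_levels):
                mean_ref = cube[:, ia, 0, ik, :].mean(axis=1)
                mean_str = cube[:, ia, 1, ik, :].mean(axis=1)
                diff = mean_str - mean_ref
                se = np.sqrt(s2 * (2.0 / n))
                with np.errstate(divide="ignore", invalid="ignore"):
                    t_stat = diff / se
                    p = 2.0 * stats.t.sf(np.abs(t_stat), df_resid)
                degenerate = s2 <= tol
                p = np.where(degenerate & (np.abs(diff) <= tol), 1.0, p)
                p = np.where(degenerate & (np.abs(diff) > tol), 0.0, p)
                rows.append(
                    pd.DataFrame(
                        {
                            "gene_id": genes,
                            "genotype": geno,
                            "tissue": tis,
                            "contrast": contrast_label(geno, tis),
                            "log2_fc": diff,
                            "fold_change": signed_fold_change(diff),
                            "p_value": p,
                        }
                    )
                )
        contrasts = pd.concat(rows, ignore_index=True)
        return FactorialAnovaResults(
            study=self.study,
            f_values=f_frame,
            p_values=p_frame,
            contrasts=contrasts,
            df_resid=df_resid,
        )


@dataclass
class FactorialAnovaResults:
    """Fitted per-gene ANOVA: term tests plus per-contrast condition tests."""

    study: ExpressionStudy
    f_values: pd.DataFrame  # genes x terms
    p_values: pd.DataFrame  # genes x terms
    contrasts: pd.DataFrame  # long: gene_id, genotype, tissue, fc, p
    df_resid: int

    def summary(self, max_genes: int = 10) -> str:
        lines = [
            "Per-gene three-way ANOVA "
            f"({len(self.p_values)} genes, residual df={self.df_resid})",
            "",
            "Term p-values (first genes):",
            self.p_values.head(max_genes).to_string(float_format="%.3g"),
            "",
            "Condition contrasts (first rows):",
            self.contrasts.head(max_genes).to_string(
                index=False, float_format="%.3g"
            ),
        ]
        return "\n".join(lines)

    def deg_records(
        self,
        fc_threshold: float = 1.5,
        alpha: float = 0.05,
        p_source: str = "contrast",
        bh: bool = False,
    ) -> pd.DataFrame:
        """Per gene x contrast table with direction calls applied."""
        if fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if not 0 < alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        recs = self.contrasts.copy()
        if p_source == "contrast":
            p = recs["p_value"].to_numpy()
        elif p_source == "condition_main_effect":
            p = self.p_values["condition"].reindex(recs["gene_id"]).to_numpy()
        else:
            raise ValueError(f"unknown p_source {p_source!r}")
        if bh:
            from statsmodels.stats.multitest import multipletests

            adj = np.empty_like(p)
            for label in recs["contrast"].unique():
                m = (recs["contrast"] == label).to_numpy()
                adj[m] = multipletests(p[m], method="fdr_bh")[1]
            p = adj
        recs["p_used"] = p
        fc = recs["fold_change"].to_numpy()
        sig = p < alpha
        up = sig & (fc >= fc_threshold)
        down = sig & (fc <= -fc_threshold)
        recs["direction"] = np.select([up, down], ["up", "down"], "unchanged")
        return recs

    def call_degs(
        self,
        fc_threshold: float = 1.5,
        alpha: float = 0.05,
        p_source: str = "contrast",
        bh: bool = False,
    ) -> list[DegSet]:
        """Direction-labelled DEG sets, one up and one down per contrast.

        The fold-change boundary is inclusive ("at least ±1.5"); the p-value
        boundary is strict (p < alpha).
        """
        recs = self.deg_records(fc_threshold, alpha, p_source, bh)
        sets = []
        for label in recs["contrast"].unique():
            sub = recs[recs["contrast"] == label]
            for direction in ("up", "down"):
                ids = set(sub.loc[sub["direction"] == direction, "gene_id"])
                sets.append(DegSet(contrast=label, direction=direction,
                                   gene_ids=ids))
        return sets


def fit_anova_per_gene(study: ExpressionStudy) -> FactorialAnovaResults:
    """Convenience wrapper: fit the per-gene factorial ANOVA."""
    return FactorialAnova(study).fit()


def call_degs(
    study: ExpressionStudy,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    p_source: str = "contrast",
    bh: bool = False,
) -> list[DegSet]:
    """Fit the ANOVA and apply the fold-change / p-value DEG filter."""
    return fit_anova_per_gene(study).call_degs(fc_threshold, alpha, p_source, bh)


def get_deg_set(sets: list[DegSet], contrast: str, direction: str) -> DegSet:
    for s in sets:
        if s.contrast == contrast and s.direction == direction:
            return s
    available = sorted({s.contrast for s in sets})
    raise KeyError(
        f"no DEG set for contrast {contrast!r}; available: {available}"
    )
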