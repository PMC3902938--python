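"""Translation-state calling from polysome/monosome log2-intensity data.

A gene's *translation state* (ts) under one condition is the log2 ratio of
its polysome- to monosome-fraction intensity, averaged over replicates.
The *change in translation state* is ``delta = ts_stress - ts_control``,
i.e. the log2 of the ratio of the two polysome:monosome ratios, so
``|delta| > 1`` marks a 2-fold change in absolute ratios.  Significance of
the stress-dependent shift is assessed with a per-gene two-factor
(condition x fraction) linear model whose interaction term is exactly the
delta contrast, optionally with empirical-Bayes moderation of the residual
variance; genes are then classified up / down / unchanged by a joint
threshold on delta and the BH-adjusted interaction p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import CONDITIONS, EXPRESSION_COLUMNS, FRACTIONS

logger = logging.getLogger(__name__)

LABELS = ("up", "down", "unchanged")


class ExpressionMatrix:
    """Gene x (condition, fraction, replicate) log2 intensities.

    Stored as a wide DataFrame indexed by gene with a 3-level column
    MultiIndex (condition, fraction, replicate).  Missing design cells are
    NaN; :meth:`incomplete_genes` lists genes missing any required
    (condition, fraction) cell.
    """

    def __init__(self, data: pd.DataFrame):
        if data.columns.nlevels != 3:
            raise ValueError(
                "expected columns MultiIndex (condition, fraction, replicate)"
            )
        self.data = data.sort_index(axis=1)
        vals = self.data.to_numpy()
        if not np.all(np.isfinite(vals) | np.isnan(vals)):
            raise ValueError("intensities must be finite (or missing)")

    # -- construction -------------------------------------------------
    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        wide = df.pivot_table(
            index="gene",
            columns=["condition", "fraction", "replicate"],
            values="log2_intensity",
            aggfunc="first",
        )
        wide.index = wide.index.astype(str)
        return cls(wide)

    def to_long(self) -> pd.DataFrame:
        long = self.data.stack(list(range(3)), future_stack=True).rename(
            "log2_intensity"
        ).reset_index()
        long.columns = ["gene", "condition", "fraction", "replicate", "log2_intensity"]
        long = long.dropna(subset=["log2_intensity"])
        return long.sort_values(EXPRESSION_COLUMNS[:4], ignore_index=True)

    # -- accessors ----------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.data.index

    def __len__(self) -> int:
        return len(self.data)

    def cell(self, condition: str, fraction: str) -> pd.DataFrame:
        """Replicate columns for one (condition, fraction) cell."""
        return self.data.loc[:, (condition, fraction)]

    def cell_mean(self, condition: str, fraction: str) -> pd.Series:
        return self.cell(condition, fraction).mean(axis=1)

    def has_fraction(self, fraction: str) -> bool:
        fracs = self.data.columns.get_level_values(1)
        return fraction in set(fracs)

    def incomplete_genes(self) -> pd.Index:
        """Genes missing every replicate of some present (condition, fraction)."""
        mask = pd.Series(False, index=self.genes)
        for cond in CONDITIONS:
            for frac in FRACTIONS:
                if (cond, frac) in {
                    (c, f) for c, f, _ in self.data.columns
                }:
                    mask |= self.cell(cond, frac).isna().all(axis=1)
        return self.genes[mask]


# ---------------------------------------------------------------------------
# Translation state and the interaction test
# ---------------------------------------------------------------------------


def compute_translation_states(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene ts_control, ts_stress and delta = ts_stress - ts_control.

    ts = mean(log2 polysome) - mean(log2 monosome) within a condition;
    delta is algebraically the log2 of the ratio of the two
    polysome:monosome ratios of per-condition geometric means.  Genes with
    an entirely missing monosome or polysome cell are excluded and logged.
    """
    parts = {}
    for cond in CONDITIONS:
        parts[cond] = m.cell_mean(cond, "polysome") - m.cell_mean(cond, "monosome")
    out = pd.DataFrame(
        {"ts_control": parts["control"], "ts_stress": parts["stress"]}
    )
    out["delta"] = out["ts_stress"] - out["ts_control"]
    complete = out.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning(
            "translation states: excluded %d gene(s) with incomplete "
            "monosome/polysome cells", n_dropped
        )
    out = out.loc[complete]
    out.index.name = "gene"
    return out


def _design_arrays(m: ExpressionMatrix) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Stack the 2x2 (condition x {monosome, polysome}) replicate blocks."""
    cells = [
        (cond, frac) for cond in CONDITIONS for frac in ("monosome", "polysome")
    ]
    blocks = []
    widths = []
    for cond, frac in cells:
        block = m.cell(cond, frac).to_numpy(dtype=float)
        if block.shape[1] < 2:
            raise ValueError(
                "interaction test requires >= 2 replicates per "
                f"(condition, fraction) cell; got {block.shape[1]} for "
                f"({cond}, {frac})"
            )
        blocks.append(block)
        widths.append(block.shape[1])
    return blocks, cells


def interaction_test(
    m: ExpressionMatrix,
    moderation: bool = True,
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Condition x fraction interaction p-value for every complete gene.

    Fits, per gene, the two-factor linear model on the monosome/polysome
    cells; the interaction contrast is
    ``(P_s - M_s) - (P_c - M_c)`` (equal to delta) and is tested against
    the pooled residual variance.  With ``moderation`` the residual
    variance is shrunk toward the across-gene mean with ``prior_df``
    pseudo-replicates before forming the t statistic (degrees of freedom
    increase accordingly) — a fixed-prior empirical-Bayes scheme that
    stabilises small-n variance estimates.

    Returns a DataFrame with columns delta, se, t, df, p_interaction.
    """
    blocks, _ = _design_arrays(m)
    means = np.column_stack([b.mean(axis=1) for b in blocks])  # Mc, Pc, Ms, Ps
    ns = np.array([b.shape[1] for b in blocks], dtype=float)
    # residual sum of squares pooled across the four cells
    rss = np.zeros(len(m))
    for b, mean_col in zip(blocks, means.T):
        rss += np.nansum((b - mean_col[:, None]) ** 2, axis=1)
    df_resid = float(ns.sum() - 4)
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom; need >= 2 replicates")
    complete = ~np.isnan(means).any(axis=1)
    s2 = rss / df_resid
    contrast = (means[:, 3] - means[:, 2]) - (means[:, 1] - means[:, 0])
    c2 = float((1.0 / ns).sum())  # variance multiplier of the contrast

    if moderation:
        if prior_df < 0:
            raise ValueError("prior_df must be >= 0")
        s2_prior = float(np.nanmean(s2[complete]))
        s2_post = (prior_df * s2_prior + df_resid * s2) / (prior_df + df_resid)
        df_total = df_resid + prior_df
    else:
        s2_post = s2
        df_total = df_resid

    se = np.sqrt(s2_post * c2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = contrast / se
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    out = pd.DataFrame(
        {
            "delta": contrast,
            "se": se,
            "t": t,
            "df": df_total,
            "p_interaction": p,
        },
        index=m.genes,
    )
    out.index.name = "gene"
    return out.loc[complete]


def classify_transcripts(
    stats_df: pd.DataFrame, tau: float = 1.0, alpha: float = 0.01
) -> pd.DataFrame:
    """Label genes up / down / unchanged from delta and the interaction q.

    up requires delta > tau (strict) and q <= alpha; down requires
    delta < -tau and q <= alpha; everything else is unchanged.  BH
    adjustment is applied across all tested genes.
    """
    from .enrichment import bh_adjust

    if tau <= 0:
        raise ValueError("tau must be > 0")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    out = stats_df.copy()
    out["q_interaction"] = bh_adjust(out["p_interaction"].to_numpy())
    sig = out["q_interaction"] <= alpha
    label = np.where(
        (out["delta"] > tau) & sig,
        "up",
        np.where((out["delta"] < -tau) & sig, "down", "unchanged"),
    )
    out["label"] = label
    return out


@dataclass
class PotentiationResult:
    """Correlation between transcriptional and translational change,
    plus transcript-level rank-sum comparisons of the translational
    classes (stress-condition total-fraction levels)."""

    r: float
    r_pvalue: float
    n: int
    ranksum_up_vs_unchanged: float | None = None
    ranksum_up_p: float | None = None
    ranksum_down_vs_unchanged: float | None = None
    ranksum_down_p: float | None = None


def potentiation_correlation(
    m: ExpressionMatrix, calls: pd.DataFrame
) -> PotentiationResult:
    """Pearson r between total-fraction change and delta, and Wilcoxon
    rank-sum tests of stress transcript levels (up vs unchanged, down vs
    unchanged)."""
    if not m.has_fraction("total"):
        raise ValueError("total-fraction values required")
    tx_change = m.cell_mean("stress", "total") - m.cell_mean("control", "total")
    joined = pd.DataFrame({"tx_change": tx_change}).join(calls, how="inner").dropna(
        subset=["tx_change", "delta"]
    )
    if len(joined) < 3:
        raise ValueError("need at least 3 genes with total-fraction data")
    r, p = stats.pearsonr(joined["tx_change"], joined["delta"])
    result = PotentiationResult(r=float(r), r_pvalue=float(p), n=len(joined))

    level_stress = m.cell_mean("stress", "total")
    if "label" in joined:
        groups = {
            lab: level_stress.reindex(joined.index[joined["label"] == lab]).dropna()
            for lab in LABELS
        }
        if len(groups["unchanged"]) and len(groups["up"]):
            stat, pv = stats.ranksums(groups["up"], groups["unchanged"])
            result.ranksum_up_vs_unchanged = float(stat)
            result.ranksum_up_p = float(pv)
        if len(groups["unchanged"]) and len(groups["down"]):
            stat, pv = stats.ranksums(groups["down"], groups["unchanged"])
            result.ranksum_down_vs_unchanged = float(stat)
            result.ranksum_down_p = float(pv)
    return result


# ---------------------------------------------------------------------------
# Estimator wrapper
# ---------------------------------------------------------------------------


class TranslationStateCaller(BaseEstimator):
    """Call per-gene translation states from an :class:`ExpressionMatrix`.

    Parameters
    ----------
    tau : float, default 1.0
        Threshold on |delta| (log2 change in translation state); 1.0 is a
        2-fold change in absolute polysome:monosome ratios.
    alpha : float, default 0.01
        Threshold on the BH-adjusted interaction p-value.
    moderation : bool, default True
        Apply empirical-Bayes shrinkage of the residual variance.
    prior_df : float, default 4.0
        Prior degrees of freedom of the shrinkage.

    Attributes
    ----------
    calls_ : DataFrame with ts_control, ts_stress, delta, p_interaction,
        q_interaction, label per tested gene.
    counts_ : dict of class label -> gene count.
    n_excluded_ : genes dropped for incomplete design cells.
    """

    def __init__(
        self,
        tau: float = 1.0,
        alpha: float = 0.01,
        moderation: bool = True,
        prior_df: float = 4.0,
    ):
        self.tau = tau
        self.alpha = alpha
        self.moderation = moderation
        self.prior_df = prior_df

    def fit(self, X: ExpressionMatrix, y=None) -> "TranslationStateCaller":
        ts = compute_translation_states(X)
        tests = interaction_test(
            X, moderation=self.moderation, prior_df=self.prior_df
        )
        stats_df = ts.join(tests[["p_interaction"]], how="inner")
        calls = classify_transcripts(stats_df, tau=self.tau, alpha=self.alpha)
        self.calls_ = calls[
            ["ts_control", "ts_stress", "delta", "p_interaction",
             "q_interaction", "label"]
        ]
        self.counts_ = {
            lab: int((calls["label"] == lab).sum()) for lab in LABELS
        }
        self.n_excluded_ = len(X) - len(calls)
        return self

    def fit_predict(self, X: ExpressionMatrix, y=None) -> pd.Series:
        return self.fit(X).calls_["label"]
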