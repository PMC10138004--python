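"""Composite coupling score: normalized geometric mean of CRQA + MI.

For one *target* record and a set of candidate records, each pair is
analyzed in a shared phase space (best-match embedding parameters),
yielding the four CRQA indices RR, DET, LAM, MDL, plus the mutual
information of the raw aligned records.  Within a panel each index is
min-max normalized across candidates and the per-candidate score is the
geometric mean of the five normalized indices — so a score lives in
[0, 1] and a candidate must do well on *every* index to score high.

Because min-max normalization absorbs any common affine rescaling of an
index (including the MI log base), the ranking does not depend on such
conventions.  An optional floor lifts normalized values off exact zero
so one worst index does not annihilate a score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .config import AnalysisConfig
from .crqa_metrics import crqa
from .cross_recurrence import cross_recurrence_matrix
from .info_entropy import series_mutual_information
from .io import StationDataset
from .phase_space import (
    EmbeddingParams,
    TimeSeries,
    embed,
    resolve_best_match,
    select_embedding_params,
)

logger = logging.getLogger(__name__)

__all__ = [
    "INDEX_COLUMNS",
    "CouplingPanel",
    "LengthSensitivity",
    "pair_metrics",
    "build_panel",
    "min_max_normalize",
    "normalize_panels",
    "geometric_mean_score",
    "length_sensitivity",
    "render_heatmap",
]

INDEX_COLUMNS = ["rr", "det", "lam", "mdl", "mi"]


@dataclass
class CouplingPanel:
    """Raw and (optionally) normalized indices for one target's candidates."""

    target: tuple[str, str]
    table: pd.DataFrame  # columns: station, factor, rr, det, lam, mdl, mi, ...
    normalized: pd.DataFrame | None = None
    scores: pd.Series | None = None

    def ranking(self) -> pd.DataFrame:
        """Candidates ordered by descending score, factor name breaking ties."""
        if self.scores is None:
            raise ValueError("panel not normalized yet; call min_max_normalize")
        out = self.table[["station", "factor"]].copy()
        out["score"] = self.scores.to_numpy()
        return out.sort_values(
            ["score", "factor"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)


def _select(series: TimeSeries, cfg: AnalysisConfig) -> EmbeddingParams:
    return select_embedding_params(
        series,
        max_delay=cfg.max_delay,
        ami_bins=cfg.ami_bins,
        max_dim=cfg.max_dim,
        rtol=cfg.fnn_rtol,
        atol=cfg.fnn_atol,
        threshold=cfg.fnn_threshold,
        max_points=cfg.fnn_max_points,
    )


def pair_metrics(
    target_series: TimeSeries,
    other_series: TimeSeries,
    config: AnalysisConfig | None = None,
    params_target: EmbeddingParams | None = None,
    params_other: EmbeddingParams | None = None,
    matrix_hook=None,
) -> dict:
    """All five raw indices for one pair of records.

    The records are z-scored before embedding (configurable) so that the
    joint threshold is not dominated by unit differences; MI is computed
    on the raw aligned records (equal-width binning is affine-invariant,
    so this matches the standardized result anyway).  ``matrix_hook``,
    when given, receives the cross-recurrence matrix before it is
    discarded (used for rendering).
    """
    cfg = config or AnalysisConfig()
    if len(target_series) != len(other_series):
        raise ValueError("paired series must have equal length")
    a = target_series.standardized() if cfg.standardize else target_series
    b = other_series.standardized() if cfg.standardize else other_series
    pa = params_target if params_target is not None else _select(a, cfg)
    pb = params_other if params_other is not None else _select(b, cfg)
    shared = resolve_best_match(pa, pb)
    matrix = cross_recurrence_matrix(
        embed(a, shared), embed(b, shared), cfg.epsilon_fraction, cfg.norm
    )
    metrics = crqa(matrix, cfg.lmin, cfg.vmin)
    if matrix_hook is not None:
        matrix_hook(matrix)
    mi = series_mutual_information(target_series, other_series, cfg.mi_bins)
    return {
        "rr": metrics.rr,
        "det": metrics.det,
        "lam": metrics.lam,
        "mdl": metrics.mdl,
        "mi": mi,
        "epsilon": matrix.epsilon,
        "params": shared,
    }


def build_panel(
    target: tuple[str, str],
    candidates: list[tuple[str, str]],
    dataset: StationDataset,
    config: AnalysisConfig | None = None,
    params_cache: dict | None = None,
    matrix_hook=None,
) -> CouplingPanel:
    """One row of raw indices per candidate against the target record.

    Degenerate (constant) candidates are skipped with a warning.
    ``params_cache`` maps (station, factor) to embedding parameters and
    is filled as a side effect, so repeated panels over one dataset do
    not re-fit AMI/FNN per series.

    With ``config.param_scope == "panel"`` the best-match rule is applied
    across the target *and every candidate*, giving one shared parameter
    pair for the whole panel; the per-candidate indices then live in one
    common phase space and are directly comparable.  The default
    ``"pair"`` resolves parameters per (target, candidate) pair, which
    mirrors per-pair reporting but lets the embedding dimension (and so
    the recurrence density) vary across the panel's rows.
    """
    cfg = config or AnalysisConfig()
    if not candidates:
        raise ValueError("need at least one candidate series")
    cache = params_cache if params_cache is not None else {}
    target_ts = dataset.get(*target)
    if target_ts.is_constant:
        raise ValueError(f"target series {target_ts.label!r} is constant")
    target_std = target_ts.standardized() if cfg.standardize else target_ts
    if target not in cache:
        cache[target] = _select(target_std, cfg)
    usable = []
    for cand in candidates:
        ts = dataset.get(*cand)
        if ts.is_constant:
            logger.warning("skipping degenerate candidate %s:%s", *cand)
            continue
        if cand not in cache:
            cache[cand] = _select(ts.standardized() if cfg.standardize else ts, cfg)
        usable.append((cand, ts))
    if cfg.param_scope == "panel":
        shared = cache[target]
        for cand, _ in usable:
            shared = resolve_best_match(shared, cache[cand])
        params_of = lambda cand: (shared, shared)  # noqa: E731
    else:
        params_of = lambda cand: (cache[target], cache[cand])  # noqa: E731
    rows = []
    for cand, ts in usable:
        hook = None
        if matrix_hook is not None:
            hook = lambda m, _cand=cand: matrix_hook(m, _cand)  # noqa: E731
        p_t, p_o = params_of(cand)
        metrics = pair_metrics(
            target_ts,
            ts,
            cfg,
            params_target=p_t,
            params_other=p_o,
            matrix_hook=hook,
        )
        rows.append(
            {
                "station": cand[0],
                "factor": cand[1],
                "rr": metrics["rr"],
                "det": metrics["det"],
                "lam": metrics["lam"],
                "mdl": metrics["mdl"],
                "mi": metrics["mi"],
                "epsilon": metrics["epsilon"],
                "params": str(metrics["params"]),
            }
        )
    if not rows:
        raise ValueError("all candidate series were degenerate")
    return CouplingPanel(target, pd.DataFrame(rows))


def geometric_mean_score(values) -> float:
    """Geometric mean of nonnegative index values; 0 if any value is 0."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty index row")
    if np.any(x < 0):
        raise ValueError("indices must be nonnegative")
    return float(np.prod(x) ** (1.0 / x.size))


def _normalize_columns(table: pd.DataFrame, floor: float) -> pd.DataFrame:
    norm = pd.DataFrame(index=table.index)
    for col in INDEX_COLUMNS:
        x = table[col].to_numpy(dtype=float)
        spread = x.max() - x.min()
        norm[col] = np.ones_like(x) if spread == 0 else (x - x.min()) / spread
    if floor > 0:
        norm[INDEX_COLUMNS] = norm[INDEX_COLUMNS].clip(lower=floor)
    return norm


def min_max_normalize(panel: CouplingPanel, floor: float = 0.0) -> CouplingPanel:
    """Min-max normalize each index across the panel and attach scores.

    A constant column maps to all ones (every candidate equally good on
    that index).  Returns a new panel; the raw table is untouched.
    """
    norm = _normalize_columns(panel.table, floor)
    scores = norm[INDEX_COLUMNS].apply(geometric_mean_score, axis=1)
    scores.name = "score"
    return CouplingPanel(panel.target, panel.table, norm, scores)


def normalize_panels(
    panels: list[CouplingPanel], scope: str = "panel", floor: float = 0.0
) -> list[CouplingPanel]:
    """Normalize several panels either independently or over pooled rows.

    ``scope="panel"`` mirrors per-panel heatmap coloring; ``"global"``
    pools all rows (e.g. 3 stations x 7 candidates) before min-max so
    scores are comparable across panels.
    """
    if scope == "panel":
        return [min_max_normalize(p, floor) for p in panels]
    if scope != "global":
        raise ValueError(f"unknown normalization scope {scope!r}")
    pooled = pd.concat([p.table for p in panels], ignore_index=True)
    norm = _normalize_columns(pooled, floor)
    scores = norm[INDEX_COLUMNS].apply(geometric_mean_score, axis=1)
    out, offset = [], 0
    for p in panels:
        k = len(p.table)
        sl = slice(offset, offset + k)
        out.append(
            CouplingPanel(
                p.target,
                p.table,
                norm.iloc[sl].reset_index(drop=True),
                scores.iloc[sl].reset_index(drop=True).rename("score"),
            )
        )
        offset += k
    return out


@dataclass
class LengthSensitivity:
    """Composite scores recomputed on truncated records."""

    target: tuple[str, str]
    lengths: list[int]
    scores: pd.DataFrame  # index: (station, factor); one column per length
    spearman: dict[int, float]  # rank correlation of each length vs full


def length_sensitivity(
    dataset: StationDataset,
    target: tuple[str, str],
    candidates: list[tuple[str, str]],
    lengths=(2000, 3000, None),
    config: AnalysisConfig | None = None,
) -> LengthSensitivity:
    """Recompute the panel on record prefixes and compare rankings.

    ``None`` in ``lengths`` stands for the full record, which is always
    included as the reference.  The Spearman entry for a truncation is
    the rank correlation of its scores against the full-record scores.
    """
    cfg = config or AnalysisConfig()
    full = dataset.n_samples
    resolved = sorted({full if L is None else int(L) for L in lengths} | {full})
    if resolved[0] < 2:
        raise ValueError(f"record length {resolved[0]} too short")
    if resolved[-1] > full:
        raise ValueError(
            f"requested length {resolved[-1]} exceeds the record ({full} samples)"
        )
    panels: dict[int, CouplingPanel] = {}
    for L in resolved:
        ds = dataset if L == full else dataset.truncated(L)
        panels[L] = min_max_normalize(
            build_panel(target, candidates, ds, cfg), floor=cfg.score_floor
        )
    reference = panels[full].scores.to_numpy()
    spearman = {}
    for L in resolved:
        scores_l = panels[L].scores.to_numpy()
        if L == full:
            spearman[L] = 1.0
        elif np.ptp(scores_l) == 0 or np.ptp(reference) == 0:
            # ranks undefined on a constant panel; equal vectors still agree
            spearman[L] = 1.0 if np.array_equal(scores_l, reference) else float("nan")
        else:
            rho = spearmanr(scores_l, reference).statistic
            spearman[L] = float(rho)
    scores = pd.DataFrame(
        {L: panels[L].scores.to_numpy() for L in resolved},
        index=pd.MultiIndex.from_frame(panels[full].table[["station", "factor"]]),
    )
    return LengthSensitivity(target, resolved, scores, spearman)


def render_heatmap(panels, path, annotate: bool = True) -> None:
    """Render one column of scores per panel, darker = stronger coupling."""
    import matplotlib.pyplot as plt

    if isinstance(panels, CouplingPanel):
        panels = [panels]
    for p in panels:
        if p.scores is None:
            raise ValueError("normalize panels before rendering")
    fig, axes = plt.subplots(
        1, len(panels), figsize=(2.2 * len(panels) + 1, 0.45 * max(len(p.table) for p in panels) + 1.5),
        squeeze=False,
    )
    for ax, p in zip(axes[0], panels):
        col = p.scores.to_numpy()[:, None]
        ax.imshow(col, cmap="Greys", vmin=0.0, vmax=1.0, aspect="auto")
        ax.set_xticks([])
        ax.set_yticks(range(len(p.table)))
        ax.set_yticklabels(p.table["factor"])
        station = p.table["station"].iloc[0] if p.table["station"].nunique() == 1 else "mixed"
        ax.set_title(f"{station}\nvs {p.target[0]}:{p.target[1]}", fontsize=9)
        if annotate:
            for k, v in enumerate(col[:, 0]):
                ax.text(
                    0, k, f"{v:.2f}", ha="center", va="center", fontsize=8,
                    color="white" if v > 0.5 else "black",
                )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
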