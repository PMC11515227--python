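"""Renderer-agnostic funnel-plot geometry plus matplotlib rendering.

Three variants:

* contour-enhanced funnel (log OR vs inverted standard error, with shaded
  study-level significance bands) — distinguishes bias from asymmetry caused
  by missing *non-significant* studies;
* trim-and-fill funnel (observed plus imputed mirror studies);
* sample-size funnel (log OR vs total N), a sensitivity analysis for the
  small samples typical of adverse-event data.

Geometry is computed as plain arrays so every coordinate is testable without
a plotting backend; :func:`render` draws SVG/PNG deterministically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core import InvalidInputError, StudyEffect, pool_random, pool_fixed
from .trimfill import TrimFillResult

#: Contour levels aligned with the alpha = 0.1 IPB significance threshold.
DEFAULT_P_LEVELS = (0.1, 0.05, 0.01)


@dataclass(frozen=True)
class FunnelPoint:
    x: float  # log OR
    y: float  # se or N, depending on axis
    tag: str  # "observed" | "filled"


@dataclass(frozen=True)
class ContourBand:
    p_level: float
    y_grid: np.ndarray  # se or N values
    x_neg: np.ndarray  # left boundary polyline
    x_pos: np.ndarray  # right boundary polyline


@dataclass(frozen=True)
class FunnelGeometry:
    points: tuple[FunnelPoint, ...]
    y_axis: str  # "standard_error_inverted" | "sample_size"
    center_line: float
    contour_bands: tuple[ContourBand, ...]  # ordered by decreasing p
    pseudo_ci: Optional[ContourBand] = None


def _pool_center(studies: Sequence[StudyEffect]) -> float:
    if len(studies) == 1:
        return studies[0].y
    return pool_random(studies).mu


def contour_funnel(
    studies: Sequence[StudyEffect],
    p_levels: Sequence[float] = DEFAULT_P_LEVELS,
    mu: Optional[float] = None,
    n_grid: int = 200,
) -> FunnelGeometry:
    """Contour-enhanced funnel: log OR vs se with significance bands.

    The band boundary at level p is |x| = z_{1-p/2} * se, so a study lies on
    the p-boundary exactly when its two-sided Wald p-value equals p.
    """
    if len(studies) < 1:
        raise InvalidInputError("funnel needs at least one study")
    se_max = 1.05 * max(s.se for s in studies)
    se_grid = np.linspace(0.0, se_max, n_grid)
    bands = tuple(
        ContourBand(
            p_level=p,
            y_grid=se_grid,
            x_neg=-stats.norm.ppf(1 - p / 2.0) * se_grid,
            x_pos=stats.norm.ppf(1 - p / 2.0) * se_grid,
        )
        for p in sorted(p_levels, reverse=True)
    )
    center = mu if mu is not None else _pool_center(studies)
    points = tuple(FunnelPoint(s.y, s.se, "observed") for s in studies)
    ci = ContourBand(0.05, se_grid, center - 1.959963984540054 * se_grid,
                     center + 1.959963984540054 * se_grid)
    return FunnelGeometry(points, "standard_error_inverted", float(center), bands, ci)


def trimfill_funnel(
    studies: Sequence[StudyEffect],
    result: TrimFillResult,
    p_levels: Sequence[float] = DEFAULT_P_LEVELS,
) -> FunnelGeometry:
    """Funnel of observed plus trim-and-fill imputed studies.

    The centre line sits at the bias-adjusted pooled estimate.
    """
    if result.pooled_adjusted.k != len(studies) + result.k0:
        raise InvalidInputError("trim-and-fill result does not match the study list")
    base = contour_funnel(
        list(studies) + list(result.filled_studies),
        p_levels=p_levels,
        mu=result.pooled_adjusted.mu,
    )
    points = tuple(FunnelPoint(s.y, s.se, "observed") for s in studies) + tuple(
        FunnelPoint(s.y, s.se, "filled") for s in result.filled_studies
    )
    return FunnelGeometry(points, base.y_axis, base.center_line, base.contour_bands,
                          base.pseudo_ci)


def samplesize_variance_constant(studies: Sequence[StudyEffect]) -> float:
    """Calibration constant c of the Var(y) ~ c/N model: median of N_i * se_i^2."""
    return float(np.median([s.n_total * s.se**2 for s in studies]))


def samplesize_funnel(
    studies: Sequence[StudyEffect],
    p_levels: Sequence[float] = DEFAULT_P_LEVELS,
    mu: Optional[float] = None,
    n_grid: int = 200,
) -> FunnelGeometry:
    """Sample-size funnel: log OR vs total N.

    Significance contours need a variance-versus-N model; we use the
    data-calibrated approximation Var(y) = c/N with c the median of
    N_i * se_i^2, giving boundaries x = +/- z_{1-p/2} * sqrt(c/N).
    """
    if len(studies) < 2:
        raise InvalidInputError("sample-size funnel needs at least two studies")
    c = samplesize_variance_constant(studies)
    n_max = 1.05 * max(s.n_total for s in studies)
    n_min = 0.5 * min(s.n_total for s in studies)
    n_vals = np.linspace(n_min, n_max, n_grid)
    bands = tuple(
        ContourBand(
            p_level=p,
            y_grid=n_vals,
            x_neg=-stats.norm.ppf(1 - p / 2.0) * np.sqrt(c / n_vals),
            x_pos=stats.norm.ppf(1 - p / 2.0) * np.sqrt(c / n_vals),
        )
        for p in sorted(p_levels, reverse=True)
    )
    center = mu if mu is not None else _pool_center(studies)
    points = tuple(FunnelPoint(s.y, s.n_total, "observed") for s in studies)
    return FunnelGeometry(points, "sample_size", float(center), bands, None)


def geometry_to_dict(geom: FunnelGeometry) -> dict:
    """JSON-serializable export of a funnel geometry."""
    return {
        "y_axis": geom.y_axis,
        "center_line": geom.center_line,
        "points": [{"x": p.x, "y": p.y, "tag": p.tag} for p in geom.points],
        "contour_bands": [
            {
                "p_level": b.p_level,
                "y_grid": b.y_grid.tolist(),
                "x_neg": b.x_neg.tolist(),
                "x_pos": b.x_pos.tolist(),
            }
            for b in geom.contour_bands
        ],
    }


def export_geometry(geom: FunnelGeometry, path) -> None:
    with open(path, "w") as fh:
        json.dump(geometry_to_dict(geom), fh, indent=1)


_BAND_GREYS = ("0.92", "0.80", "0.65")


def render(geom: FunnelGeometry, path, fmt: Optional[str] = None,
           title: Optional[str] = None) -> None:
    """Draw the funnel to an SVG or PNG file.

    Output is deterministic for identical geometry: rendering pins the SVG
    hash salt and strips the date metadata.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fmt = fmt or str(path).rsplit(".", 1)[-1].lower()
    if fmt not in ("svg", "png"):
        raise InvalidInputError(f"format must be 'svg' or 'png', got {fmt!r}")

    with matplotlib.rc_context({"svg.hashsalt": "ipbkit"}):
        fig, ax = plt.subplots(figsize=(5.0, 4.2))
        # shade between successive significance boundaries (outermost darkest)
        for i, band in enumerate(geom.contour_bands):
            grey = _BAND_GREYS[min(i, len(_BAND_GREYS) - 1)]
            nxt = geom.contour_bands[i + 1] if i + 1 < len(geom.contour_bands) else None
            for sgn in ("x_neg", "x_pos"):
                inner = getattr(band, sgn)
                outer = getattr(nxt, sgn) if nxt is not None else None
                if outer is None:
                    lim = np.sign(inner.sum() or 1.0) * (np.max(np.abs(inner)) * 1.6 + 0.5)
                    outer = np.full_like(inner, lim)
                ax.fill_betweenx(band.y_grid, inner, outer, color=grey, lw=0,
                                 label=f"p < {band.p_level:g}" if sgn == "x_pos" else None)
            ax.plot(band.x_neg, band.y_grid, color="0.4", lw=0.6)
            ax.plot(band.x_pos, band.y_grid, color="0.4", lw=0.6)
        obs = [p for p in geom.points if p.tag == "observed"]
        fil = [p for p in geom.points if p.tag == "filled"]
        if obs:
            ax.plot([p.x for p in obs], [p.y for p in obs], "o", mfc="C0", mec="k",
                    ms=5, lw=0, label="observed")
        if fil:
            ax.plot([p.x for p in fil], [p.y for p in fil], "o", mfc="none", mec="C3",
                    ms=6, lw=0, label="imputed")
        ax.axvline(geom.center_line, color="C3", lw=1.0, ls="--")
        if geom.y_axis == "standard_error_inverted":
            ax.set_ylabel("standard error")
            ax.set_ylim(max(b.y_grid.max() for b in geom.contour_bands) if geom.contour_bands
                        else max((p.y for p in geom.points), default=1.0), 0)
        else:
            ax.set_ylabel("total sample size")
        ax.set_xlabel("odds ratio (log scale)")
        xticks = ax.get_xticks()
        ax.set_xticks(xticks)
        ax.set_xticklabels([f"{math.exp(t):.2g}" for t in xticks])
        if title:
            ax.set_title(title)
        ax.legend(loc="upper right", fontsize=7, frameon=False)
        fig.tight_layout()
        fig.savefig(path, format=fmt, metadata={"Date": None} if fmt == "svg" else None)
        plt.close(fig)
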