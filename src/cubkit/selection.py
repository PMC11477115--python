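"""Mutation-versus-selection diagnostics.

* Neutrality plot: OLS regression of per-gene GC12 on GC3.  A slope near 1
  indicates mutation pressure drives all three codon positions together; a
  slope near 0 indicates selection decouples positions 1-2 from position 3.
* ENC-plot: observed ENC against GC3s, compared with the mutation-only
  reference curve; the per-gene ENC ratio (expected - observed)/expected
  summarises the vertical deviation (positive = below the curve).
* PR2-plot: per-gene (G3/(G3+C3), A3/(A3+T3)); (0.5, 0.5) is the
  mutation-only parity expectation.
* Correspondence analysis of the gene x 59-codon RSCU matrix.
* Correlation suites (Spearman by default) between codon-usage indices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .composition import codon_counts
from .sequence_io import CdsSet


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p: float
    n: int


@dataclass
class EncPlotResult:
    table: pd.DataFrame  # gene_id, GC3s, ENC_obs, ENC_exp, enc_ratio
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    frac_in_band: float


@dataclass
class Pr2Point:
    gene_id: str
    x: float  # G3 / (G3 + C3)
    y: float  # A3 / (A3 + T3)


@dataclass
class CAResult:
    row_coords: pd.DataFrame  # gene x axis, principal coordinates
    col_coords: pd.DataFrame  # codon x axis
    inertia_pct: np.ndarray
    n_axes: int
    total_inertia: float
    dropped_columns: list[str]


def neutrality_regression(
    gc12: Sequence[float], gc3: Sequence[float]
) -> RegressionResult:
    """OLS of GC12 on GC3 with Pearson r and its two-sided p-value."""
    x = np.asarray(gc3, dtype=float)
    y = np.asarray(gc12, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError("need at least 3 genes")
    if np.ptp(x) == 0:
        warnings.warn("GC3 has zero variance; slope undefined")
        return RegressionResult(
            slope=float("nan"),
            intercept=float(np.mean(y)),
            r=float("nan"),
            p=float("nan"),
            n=int(x.size),
        )
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p=float(fit.pvalue),
        n=int(x.size),
    )


def enc_plot(
    records: pd.DataFrame,
    band: tuple[float, float] = (-0.05, 0.10),
    bin_width: float = 0.05,
) -> EncPlotResult:
    """ENC-plot summary from a per-gene index table.

    ``records`` needs columns gene_id, GC3s, ENC, ENC_expected, ENC_ratio
    (as produced by :func:`cubkit.indices.build_gene_index_table`).  The
    ENC-ratio histogram uses left-closed bins of width 0.05 aligned to
    multiples of 0.05, spanning at least [-0.25, 0.30].
    """
    cols = ["gene_id", "GC3s", "ENC", "ENC_expected", "ENC_ratio"]
    table = records[cols].dropna(subset=["ENC", "ENC_ratio"]).copy()
    ratios = table["ENC_ratio"].to_numpy()
    lo = min(-0.25, math.floor(ratios.min() / bin_width) * bin_width) if ratios.size else -0.25
    hi = max(0.30, math.ceil(ratios.max() / bin_width) * bin_width) if ratios.size else 0.30
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(ratios, bins=edges)
    # np.histogram closes the last bin; nudge exact-right-edge values in
    if ratios.size and ratios.max() == edges[-1]:
        pass  # already counted in the final bin, consistent with coverage
    in_band = ((ratios >= band[0]) & (ratios <= band[1])).mean() if ratios.size else 0.0
    return EncPlotResult(
        table=table,
        bin_edges=edges,
        bin_counts=counts,
        frac_in_band=float(in_band),
    )


def pr2_plot(cds_set: CdsSet) -> tuple[list[Pr2Point], dict[str, int]]:
    """Per-gene PR2 points and quadrant counts relative to (0.5, 0.5).

    Quadrants: the x-test is G3 vs C3, the y-test A3 vs T3; genes exactly
    on a 0.5 line are assigned to the >= side.  Genes with a zero
    denominator are dropped with a warning.
    """
    points: list[Pr2Point] = []
    quadrants = {"top_left": 0, "top_right": 0, "bottom_left": 0, "bottom_right": 0}
    for gene in cds_set:
        thirds = gene.seq[2::3]
        a3, t3, g3, c3 = (thirds.count(b) for b in "ATGC")
        if g3 + c3 == 0 or a3 + t3 == 0:
            warnings.warn(f"gene {gene.id}: zero PR2 denominator, dropped")
            continue
        x = g3 / (g3 + c3)
        y = a3 / (a3 + t3)
        points.append(Pr2Point(gene_id=gene.id, x=x, y=y))
        vert = "top" if y >= 0.5 else "bottom"
        horiz = "right" if x >= 0.5 else "left"
        quadrants[f"{vert}_{horiz}"] += 1
    return points, quadrants


def correspondence_analysis(matrix: pd.DataFrame) -> CAResult:
    """Correspondence analysis of a non-negative gene x codon matrix.

    Undefined (NaN) entries are treated as 0 and all-zero columns are
    dropped.  P = N / grand total; standardized residuals
    S = Dr^{-1/2} (P - r c^T) Dc^{-1/2} are decomposed by SVD; principal
    coordinates are Dr^{-1/2} U S and Dc^{-1/2} V S; per-axis inertia is
    the squared singular value.
    """
    m = matrix.fillna(0.0).astype(float)
    if (m.to_numpy() < 0).any():
        raise ValueError("matrix must be non-negative")
    if m.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    dropped = [c for c in m.columns if m[c].sum() == 0]
    m = m.drop(columns=dropped)
    n = m.to_numpy()
    grand = n.sum()
    if grand == 0:
        raise ValueError("matrix is identically zero")
    p = n / grand
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    u, sv, vt = np.linalg.svd(s, full_matrices=False)
    keep = sv > 1e-12
    u, sv, vt = u[:, keep], sv[keep], vt[keep]
    n_axes = int(sv.size)
    inertias = sv**2
    total = float(inertias.sum())
    row_coords = (u * sv) / np.sqrt(r)[:, None]
    col_coords = (vt.T * sv) / np.sqrt(c)[:, None]
    axes = [f"axis{i + 1}" for i in range(n_axes)]
    return CAResult(
        row_coords=pd.DataFrame(row_coords, index=m.index, columns=axes),
        col_coords=pd.DataFrame(col_coords, index=m.columns, columns=axes),
        inertia_pct=(100.0 * inertias / total) if total > 0 else inertias,
        n_axes=n_axes,
        total_inertia=total,
        dropped_columns=dropped,
    )


def rscu_matrix(cds_set: CdsSet) -> pd.DataFrame:
    """Per-gene RSCU over the 59 informative codons (NaN where undefined)."""
    from .indices import rscu

    rows = {}
    for gene in cds_set:
        values = rscu(codon_counts(gene)).values
        rows[gene.id] = {
            c: (v if v is not None else np.nan) for c, v in values.items()
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def correlation_suite(
    table: pd.DataFrame,
    pairs: Iterable[tuple[str, str]],
    method: str = "spearman",
) -> pd.DataFrame:
    """Pairwise correlations with two-sided p-values.

    Missing values are excluded pairwise; each pair needs >= 4 complete
    observations.  Constant variables yield NaN rho with a warning.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    rows = []
    for x_name, y_name in pairs:
        sub = table[[x_name, y_name]].dropna()
        n = len(sub)
        if n < 4:
            raise ValueError(
                f"pair ({x_name}, {y_name}): only {n} complete observations"
            )
        x = sub[x_name].to_numpy(dtype=float)
        y = sub[y_name].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(f"pair ({x_name}, {y_name}): constant variable")
            rho, p = float("nan"), float("nan")
        elif method == "spearman":
            rho, p = stats.spearmanr(x, y)
        else:
            rho, p = stats.pearsonr(x, y)
        rows.append(
            {"variable_x": x_name, "variable_y": y_name,
             "rho": float(rho), "p": float(p), "n": n}
        )
    return pd.DataFrame(rows)


#: index-table column pairs examined in the standard correlation report
DEFAULT_CORRELATION_PAIRS: tuple[tuple[str, str], ...] = (
    ("SCUO", "at_skew"),
    ("SCUO", "gc_skew"),
    ("SCUO", "purine_skew"),
    ("SCUO", "pyrimidine_skew"),
    ("SCUO", "keto_skew"),
    ("SCUO", "amino_skew"),
    ("SCUO", "GRAVY"),
    ("SCUO", "L_aa"),
    ("SCUO", "aromaticity"),
    ("SCUO", "pI"),
    ("SCUO", "MILC"),
)

#: pairs against the first CA axis (joined after CA row coordinates)
AXIS1_CORRELATES: tuple[str, ...] = (
    "CAI", "CBI", "Fop", "GC3", "GC", "GC3s", "ENC", "L_aa",
)
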