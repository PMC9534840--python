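"""Pipeline orchestration, group summaries, figures and network exports.

Ties the stages together (curate -> fit -> summarise) and produces the
standard artefacts: a per-ego fits table, per-group eta summaries and
histograms, per-ego cumulative-curve plots with confidence bands, and
GraphML/edge-list exports of the directed grooming ego-networks.  Every
figure is backed by a machine-readable CSV holding exactly the plotted
values, so downstream checks never need to parse an image.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd

from .circles import continuum_cdf
from .curation import EgoNetwork, curate
from .estimation import ContinuumFit, empirical_cdf, fit_band, fit_ego, normalize_costs

__all__ = [
    "GroupSummary",
    "run_pipeline",
    "eta_histogram",
    "export_ego_network",
    "plot_fit",
    "fits_to_frame",
]

logger = logging.getLogger("egolayers")

FIT_COLUMNS = ["ego_id", "group_id", "L", "n_follows", "sigma", "t_bar",
               "eta_hat", "ci_low", "ci_high", "delta", "regime", "degenerate"]


@dataclass
class GroupSummary:
    """Distribution of fitted eta within one group."""

    group_id: str
    n_pre_filter: int
    n_retained: int
    n_excluded: int
    n_degenerate: int
    eta_values: list = field(default_factory=list)

    def __post_init__(self):
        if self.n_pre_filter != self.n_retained + self.n_excluded + self.n_degenerate:
            raise ValueError(
                f"group {self.group_id!r}: stage counts do not reconcile "
                f"({self.n_pre_filter} != {self.n_retained} + {self.n_excluded}"
                f" + {self.n_degenerate})"
            )

    @property
    def eta_mean(self) -> float:
        return float(np.mean(self.eta_values)) if self.eta_values else float("nan")

    def eta_mode(self, bin_width: float = 1.0) -> float:
        """Center of the fullest histogram bin (histogram-bin mode)."""
        hist = eta_histogram(self, bin_width=bin_width)
        if hist["counts"].size == 0:
            return float("nan")
        i = int(np.argmax(hist["counts"]))
        return float((hist["bin_edges"][i] + hist["bin_edges"][i + 1]) / 2.0)

    @property
    def n_inverted(self) -> int:
        return int(sum(e < 0 for e in self.eta_values))

    def n_boundary(self, fits) -> int:
        return sum(1 for f in fits
                   if f.group_id == self.group_id and f.regime == "boundary")

    def to_dict(self, bin_width: float = 1.0) -> dict:
        return {
            "group_id": self.group_id,
            "n_pre_filter": self.n_pre_filter,
            "n_retained": self.n_retained,
            "n_excluded": self.n_excluded,
            "n_degenerate": self.n_degenerate,
            "eta_mean": self.eta_mean,
            "eta_mode": self.eta_mode(bin_width),
            "n_inverted": self.n_inverted,
        }


def fits_to_frame(fits) -> pd.DataFrame:
    """Flatten :class:`ContinuumFit` records into the canonical fits table."""
    return pd.DataFrame([f.to_dict() for f in fits], columns=FIT_COLUMNS)


def run_pipeline(follows, events, mode: str = "count", min_partners: int = 5,
                 min_follow_minutes: float = 5.0, delta: float = 0.025,
                 start=None, end=None):
    """Curate the observation files and fit every retained ego.

    Returns ``(fits, summaries, exclusions, log)``: the list of
    :class:`ContinuumFit` (degenerate egos flagged, not dropped), one
    :class:`GroupSummary` per group, an exclusions DataFrame (ego, group, L,
    follows, low-effort diagnostic), and the stage-count log.  Deterministic
    given identical inputs.
    """
    retained, excluded, log = curate(
        follows, events, mode=mode, min_partners=min_partners,
        min_follow_minutes=min_follow_minutes, start=start, end=end,
    )
    fits = [fit_ego(n, delta=delta, min_partners=min_partners) for n in retained]
    for f in fits:
        if f.degenerate:
            logger.warning("ego %s: degenerate network (all weights equal)", f.ego_id)

    mean_follows = log.get("mean_follows_per_ego", 0.0) or 0.0
    exclusions = pd.DataFrame(
        [{
            "ego_id": n.ego_id, "group_id": n.group_id, "L": n.L,
            "n_follows": n.n_follows,
            # diagnostic only: most excluded individuals are under-observed
            "low_effort": bool(n.n_follows < 0.2 * mean_follows),
        } for n in excluded],
        columns=["ego_id", "group_id", "L", "n_follows", "low_effort"],
    )

    group_ids = sorted({n.group_id for n in retained} | {n.group_id for n in excluded})
    summaries = []
    for gid in group_ids:
        good = [f for f in fits if f.group_id == gid and not f.degenerate]
        n_deg = sum(1 for f in fits if f.group_id == gid and f.degenerate)
        n_exc = sum(1 for n in excluded if n.group_id == gid)
        summaries.append(GroupSummary(
            group_id=gid,
            n_pre_filter=len(good) + n_deg + n_exc,
            n_retained=len(good), n_excluded=n_exc, n_degenerate=n_deg,
            eta_values=[f.eta_hat for f in good],
        ))
    log["n_degenerate"] = sum(1 for f in fits if f.degenerate)
    return fits, summaries, exclusions, log


def eta_histogram(summary: GroupSummary, bin_width: float = 1.0) -> dict:
    """Histogram of a group's fitted eta values with the two reference lines.

    Bins are aligned to multiples of ``bin_width``; counts always sum to the
    number of fits.  ``regime_line`` marks the normal/inverted boundary at
    eta = 0 and ``mean_line`` the group mean.  An empty group returns empty
    arrays with a warning.
    """
    values = np.asarray(summary.eta_values, dtype=float)
    if values.size == 0:
        warnings.warn(f"group {summary.group_id!r} has no fits to histogram",
                      stacklevel=2)
        return {"bin_edges": np.empty(0), "counts": np.empty(0, dtype=int),
                "regime_line": 0.0, "mean_line": float("nan")}
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    return {"bin_edges": edges, "counts": counts, "regime_line": 0.0,
            "mean_line": summary.eta_mean}


def export_ego_network(network: EgoNetwork, fit: ContinuumFit, out_dir) -> dict:
    """Write one ego-network as a GraphML file plus a long-format edge list.

    Edges run ego -> alter with the grooming weight as attribute; eta and the
    regime are stored as graph attributes (NaN eta for degenerate fits is
    stored as the string "degenerate" only in the regime field).  The GraphML
    round-trips through :func:`networkx.read_graphml` attribute-exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g = nx.DiGraph()
    g.graph["ego_id"] = network.ego_id
    g.graph["group_id"] = network.group_id
    g.graph["regime"] = fit.regime
    if np.isfinite(fit.eta_hat):
        g.graph["eta"] = float(fit.eta_hat)
    g.add_node(network.ego_id, role="ego")
    for alter in network.alters:
        g.add_node(alter, role="alter")
        g.add_edge(network.ego_id, alter, weight=float(network.weights[alter]))
    graphml_path = out / f"{network.ego_id}.graphml"
    nx.write_graphml(g, graphml_path)

    edges = pd.DataFrame(
        [(network.ego_id, a, float(network.weights[a]), network.group_id)
         for a in network.alters],
        columns=["ego_id", "alter_id", "weight", "group_id"],
    )
    edges_path = out / f"{network.ego_id}_edges.csv"
    edges.to_csv(edges_path, index=False)
    return {"graphml": graphml_path, "edges": edges_path}


def plot_fit(fit: ContinuumFit, network: EgoNetwork | None = None,
             out_dir=".", grid_n: int = 101) -> dict | None:
    """Plot one ego's fitted chi(t) with data steps and confidence band.

    Writes ``<ego>_fit.png`` plus two backing CSVs holding exactly the
    plotted values: ``<ego>_fit.csv`` (t, chi, band_low, band_high on the
    evaluation grid) and, when the network is supplied, ``<ego>_ecdf.csv``
    (t, fraction empirical steps).  Degenerate fits are skipped with a log
    entry and return None.
    """
    if fit.degenerate or not np.isfinite(fit.eta_hat):
        logger.info("ego %s: degenerate fit, no plot produced", fit.ego_id)
        return None
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_grid = np.linspace(0.0, 1.0, grid_n)
    chi = np.asarray(continuum_cdf(fit.eta_hat, t_grid))
    band_low, band_high = fit_band(fit, t_grid)
    curve = pd.DataFrame({"t": t_grid, "chi": chi,
                          "band_low": band_low, "band_high": band_high})
    curve_path = out / f"{fit.ego_id}_fit.csv"
    curve.to_csv(curve_path, index=False)

    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.fill_between(t_grid, band_low, band_high, alpha=0.25, color="C0",
                    label=f"{100 * (1 - 2 * fit.delta):.0f}% band")
    ax.plot(t_grid, chi, "--", color="C0",
            label=rf"$\chi(t)$, $\eta$ = {fit.eta_hat:.2f}")
    paths = {"figure": out / f"{fit.ego_id}_fit.png", "curve": curve_path}
    if network is not None:
        points, fractions = empirical_cdf(normalize_costs(network))
        ecdf = pd.DataFrame({"t": points, "fraction": fractions})
        ecdf_path = out / f"{fit.ego_id}_ecdf.csv"
        ecdf.to_csv(ecdf_path, index=False)
        ax.plot(points, fractions, "o", color="C3", ms=4, label="data")
        paths["ecdf"] = ecdf_path
    ax.set_xlabel("normalised cost $t$")
    ax.set_ylabel(r"$\chi(t)$")
    ax.set_title(f"{fit.ego_id} ({fit.group_id})")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(paths["figure"], dpi=120)
    plt.close(fig)
    return paths
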