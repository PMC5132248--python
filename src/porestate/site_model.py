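"""Binding-site geometry and per-frame state discretization.

A site model is a strictly descending list of axial boundaries b0 > b1 >
... > b(n-1) defining n-1 sites S0..S(n-2), numbered from the extracellular
side (large z) to the intracellular side.  Site i spans the half-open
interval b[i] >= z > b[i+1] (upper-inclusive, so boundaries partition the
axis deterministically).  An optional radial cutoff excludes ions far from
the axis; by default it is unbounded, since in a real channel the pore
walls bound r sterically.

The ion-binding state of a frame is the *set* of occupied sites, labelled
canonically as e.g. ``K:0:2:4`` (species prefix, ascending site indices);
an empty pore is the apo state ``K:``.  Multiplicity is lost by the set
semantics; a multiply-occupied site triggers a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import argrelmax

__all__ = [
    "SiteModel",
    "BindingState",
    "parse_state_label",
    "state_ion_count",
    "axial_histogram",
    "suggest_boundaries",
    "assign_site",
    "frame_state",
    "discretize_trajectory",
    "write_occupancy",
    "read_occupancy",
]

log = logging.getLogger(__name__)

NONE_SITE = -1  # sentinel site index for "not in any site"


@dataclass(frozen=True)
class SiteModel:
    """Descending boundary list + optional radial cutoff for one ion species."""

    boundaries: tuple[float, ...]
    max_radius: float = np.inf
    species_label: str = "K"

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.boundaries)
        if len(b) < 2:
            raise ValueError("need at least 2 boundaries (1 site)")
        if any(hi <= lo for hi, lo in zip(b, b[1:])):
            raise ValueError("boundaries must be strictly descending")
        if not self.max_radius > 0:
            raise ValueError("max_radius must be positive")
        object.__setattr__(self, "boundaries", b)

    @property
    def n_sites(self) -> int:
        return len(self.boundaries) - 1

    def site_names(self) -> list[str]:
        return [f"S{i}" for i in range(self.n_sites)]


@dataclass(frozen=True)
class BindingState:
    """Ion species + set of occupied site indices, canonically labelled."""

    species: str
    occupied: frozenset[int]

    @property
    def label(self) -> str:
        return self.species + ":" + ":".join(str(i) for i in sorted(self.occupied))

    @property
    def n_ions(self) -> int:
        return len(self.occupied)


def parse_state_label(label: str) -> BindingState:
    """Inverse of :attr:`BindingState.label` (``"K:"`` parses to the apo state)."""
    species, _, rest = label.partition(":")
    if not species:
        raise ValueError(f"state label {label!r} lacks a species prefix")
    sites = frozenset(int(p) for p in rest.split(":") if p != "")
    return BindingState(species=species, occupied=sites)


def state_ion_count(label: str) -> int:
    """Number of occupied sites encoded in a state label."""
    return parse_state_label(label).n_ions


# ---------------------------------------------------------------------------
# axial density histogram and boundary suggestion
# ---------------------------------------------------------------------------


def axial_histogram(
    z_values: np.ndarray,
    bin_width: float = 0.25,
    range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Histogram of axial ion coordinates.

    ``density`` is counts / (N_total * bin_width) where N_total counts all
    input values, so the density integrates to the in-range fraction.
    """
    z = np.asarray(z_values, dtype=float).ravel()
    if z.size == 0:
        raise ValueError("no axial values to histogram")
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    if range is None:
        range = (float(z.min()), float(z.max()) + bin_width)
    lo, hi = range
    if not hi > lo:
        raise ValueError("histogram range must satisfy hi > lo")
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(z, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    density = counts / (z.size * bin_width)
    return pd.DataFrame({"center": centers, "count": counts, "density": density})


def suggest_boundaries(centers: np.ndarray, density: np.ndarray) -> list[float]:
    """Candidate site boundaries: density minima between successive peaks.

    Advisory only — peak separation can be ambiguous and the final boundary
    list is the user's physicochemical call.  Returns boundaries in
    descending axial order; empty (with a warning) if fewer than two peaks
    are found, which usually means the pore-axis definition needs revising.
    """
    centers = np.asarray(centers, dtype=float)
    density = np.asarray(density, dtype=float)
    if centers.size < 3:
        raise ValueError("need at least 3 bins to locate minima between peaks")
    (peaks,) = argrelmax(density, mode="clip")
    # plateau-tolerant fallback: argrelmax misses flat-topped peaks
    if peaks.size < 2:
        log.warning(
            "fewer than two density peaks found; no boundaries suggested "
            "(consider revising the pore-axis definition)"
        )
        return []
    bounds = []
    for a, b in zip(peaks, peaks[1:]):
        k = a + int(np.argmin(density[a : b + 1]))
        bounds.append(float(centers[k]))
    return sorted(bounds, reverse=True)


# ---------------------------------------------------------------------------
# state assignment
# ---------------------------------------------------------------------------


def assign_site(z, r, model: SiteModel):
    """Site index for axial/radial coordinates, or ``NONE_SITE``.

    Vectorized: scalars in, scalar out; arrays in, int array out.  Site i
    holds iff boundaries[i] >= z > boundaries[i+1] and r <= max_radius.
    """
    z_arr = np.asarray(z, dtype=float)
    r_arr = np.asarray(r, dtype=float)
    desc = np.asarray(model.boundaries)
    # descending boundaries; searchsorted needs ascending, so negate.
    # side="right" makes intervals upper-inclusive: b[i] >= z > b[i+1]
    idx = np.searchsorted(-desc, -z_arr, side="right") - 1
    site = np.where((idx >= 0) & (idx < model.n_sites), idx, NONE_SITE)
    site = np.where(r_arr <= model.max_radius, site, NONE_SITE)
    if z_arr.ndim == 0:
        return int(site)
    return site.astype(int)


def frame_state(records: pd.DataFrame, model: SiteModel) -> tuple[BindingState, dict[int, int]]:
    """Binding state of one frame plus the ion → site map.

    ``records`` must hold AxialRecord rows of a single frame (columns
    ``ion_id``, ``z_A``, ``r_A``).
    """
    frames = records["frame"].unique() if "frame" in records else [None]
    if len(frames) > 1:
        raise ValueError("records span more than one frame")
    sites = assign_site(records["z_A"].to_numpy(), records["r_A"].to_numpy(), model)
    ion_map = {
        int(i): int(s)
        for i, s in zip(records["ion_id"].to_numpy(), np.atleast_1d(sites))
    }
    in_sites = [s for s in ion_map.values() if s != NONE_SITE]
    occupied = frozenset(in_sites)
    if len(in_sites) > len(occupied):
        log.warning(
            "frame %s: multiple ions share a binding site; set semantics "
            "collapse the multiplicity",
            frames[0],
        )
    return BindingState(model.species_label, occupied), ion_map


def discretize_trajectory(records: pd.DataFrame, model: SiteModel) -> pd.DataFrame:
    """Per-frame state labels and per-ion site assignments for a whole run.

    ``records`` is the axial-trace table from
    :func:`~porestate.pore_projection.project_trajectory`.  Returns one row
    per frame with columns ``frame``, ``time_ps``, ``state`` plus the
    long-form site table is attached as ``.attrs['ion_sites']`` (columns
    frame, ion_id, site, z_A).
    """
    df = records.sort_values(["frame", "ion_id"], kind="stable").reset_index(drop=True)
    site = assign_site(df["z_A"].to_numpy(), df["r_A"].to_numpy(), model)
    df = df.assign(site=site)

    frames = df["frame"].to_numpy()
    uniq, starts = np.unique(frames, return_index=True)
    bounds = np.append(starts, len(df))
    labels: list[str] = []
    times = df["time_ps"].to_numpy()
    site_arr = df["site"].to_numpy()
    multi = 0
    for a, b in zip(bounds[:-1], bounds[1:]):
        occ = site_arr[a:b]
        occ = occ[occ != NONE_SITE]
        occ_set = np.unique(occ)
        if occ.size > occ_set.size:
            multi += 1
        labels.append(
            model.species_label + ":" + ":".join(str(int(s)) for s in occ_set)
        )
    if multi:
        log.warning("%d frames had a multiply-occupied site (set semantics)", multi)
    out = pd.DataFrame(
        {"frame": uniq, "time_ps": times[starts], "state": labels}
    )
    out.attrs["ion_sites"] = df[["frame", "time_ps", "ion_id", "z_A", "site"]]
    return out


def write_occupancy(states: pd.DataFrame, path: str | Path) -> None:
    """Occupancy TSV: frame, time_ps, state, and per-ion ``ion:site`` columns."""
    ion_sites = states.attrs.get("ion_sites")
    with open(path, "w") as fh:
        fh.write("frame\ttime_ps\tstate\tion_sites\n")
        if ion_sites is not None:
            grouped = ion_sites.groupby("frame")
            per_frame = {
                fr: ",".join(
                    f"{int(r.ion_id)}:{int(r.site)}"
                    for r in g.itertuples()
                    if r.site != NONE_SITE
                )
                for fr, g in grouped
            }
        else:
            per_frame = {}
        for row in states.itertuples():
            fh.write(
                f"{int(row.frame)}\t{row.time_ps:.6f}\t{row.state}\t"
                f"{per_frame.get(row.frame, '')}\n"
            )


def read_occupancy(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)
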