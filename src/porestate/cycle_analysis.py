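"""Cycle decomposition of the state path and per-ion permeation accounting.

In the state graph a trajectory is a single walk; anchoring at the most
stable state decomposes it into cyclic paths (anchor → ... → anchor).  The
segment before the first anchor visit is kept as a *leading partial* path
(it contains the trajectory's first frame) and the segment after the last
visit as a *trailing partial*.  A path is a conduction event when its
ion-count sequence shows at least one increase (association) and one
decrease (dissociation).

Independently of states, each ion's itinerary through the sites is tracked
to count full permeations: an ion that enters from one reservoir, passes
through binding sites, and leaves by the opposite reservoir has crossed
the membrane once.  Re-entries without a completed crossing do not count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .site_model import NONE_SITE, SiteModel, state_ion_count

__all__ = [
    "CyclicPath",
    "IonItinerary",
    "EXTRA",
    "INTRA",
    "OFFSITE",
    "extract_cycles",
    "classify_conduction",
    "ion_itineraries",
    "count_permeations",
    "write_cycles",
]

EXTRA = "extra"  # extracellular reservoir (z above the top boundary)
INTRA = "intra"  # intracellular reservoir (z below the bottom boundary)
OFFSITE = "off"  # within the axial span but outside every site (radial cutoff)


@dataclass
class CyclicPath:
    states: tuple[str, ...]
    anchored: bool
    leading_partial: bool = False
    trailing_partial: bool = False
    is_conduction: bool | None = None

    def __len__(self) -> int:
        return len(self.states)


def extract_cycles(collapsed: Sequence[str], anchor: str) -> list[CyclicPath]:
    """Split a collapsed state sequence at every anchor occurrence.

    Returns leading partial (if any), anchored cycles in order, trailing
    partial (if any).  Concatenating the pieces with shared anchors merged
    reproduces the input exactly.
    """
    seq = list(collapsed)
    hits = [i for i, s in enumerate(seq) if s == anchor]
    if not hits:
        raise ValueError(
            f"anchor state {anchor!r} never occurs in the sequence; inspect the "
            "state graph to choose a valid anchor"
        )
    paths: list[CyclicPath] = []
    if hits[0] > 0:
        paths.append(
            CyclicPath(tuple(seq[: hits[0] + 1]), anchored=False, leading_partial=True)
        )
    for a, b in zip(hits, hits[1:]):
        paths.append(CyclicPath(tuple(seq[a : b + 1]), anchored=True))
    if hits[-1] < len(seq) - 1:
        paths.append(
            CyclicPath(tuple(seq[hits[-1] :]), anchored=False, trailing_partial=True)
        )
    for p in paths:
        p.is_conduction = classify_conduction(p)
    return paths


def classify_conduction(cycle: CyclicPath | Sequence[str]) -> bool:
    """True iff the path's ion-count sequence both increases and decreases."""
    states = cycle.states if isinstance(cycle, CyclicPath) else tuple(cycle)
    counts = [state_ion_count(s) for s in states]
    diffs = np.diff(counts)
    return bool((diffs > 0).any() and (diffs < 0).any())


def write_cycles(paths: Sequence[CyclicPath], path: str | Path) -> None:
    """One path per line: comma-separated states + flags."""
    with open(path, "w") as fh:
        fh.write("states\tanchored\tleading_partial\ttrailing_partial\tconduction\n")
        for p in paths:
            fh.write(
                ",".join(p.states)
                + f"\t{int(p.anchored)}\t{int(p.leading_partial)}"
                + f"\t{int(p.trailing_partial)}\t{int(bool(p.is_conduction))}\n"
            )


# ---------------------------------------------------------------------------
# per-ion itineraries and permeation counting
# ---------------------------------------------------------------------------


@dataclass
class IonItinerary:
    """Collapsed (frame, token) visits of one ion.

    Tokens are site indices (int) or the side markers ``EXTRA``/``INTRA``
    for reservoir dwell, or ``OFFSITE`` for in-span but radially excluded
    positions.
    """

    ion_id: int
    visits: list[tuple[int, int | str]]  # (first frame of run, token)

    def tokens(self) -> list[int | str]:
        return [t for _, t in self.visits]


def _tokenize_ion(
    frames: np.ndarray, sites: np.ndarray, z: np.ndarray, model: SiteModel
) -> list[tuple[int, int | str]]:
    top = model.boundaries[0]
    bottom = model.boundaries[-1]
    visits: list[tuple[int, int | str]] = []
    for fr, s, zz in zip(frames, sites, z):
        if s != NONE_SITE:
            tok: int | str = int(s)
        elif zz > top:
            tok = EXTRA
        elif zz <= bottom:
            tok = INTRA
        else:
            tok = OFFSITE
        if not visits or visits[-1][1] != tok:
            visits.append((int(fr), tok))
    return visits


def _smooth_grazing(
    visits: list[tuple[int, int | str]],
    frame_counts: list[int],
    min_offsite_frames: int,
) -> list[tuple[int, int | str]]:
    """Drop reservoir/off-site excursions shorter than the minimum.

    An excursion of fewer than ``min_offsite_frames`` frames between two
    site visits is boundary grazing, not a real exit, and is removed so it
    neither resets nor splits the itinerary.  The default minimum of 1
    removes nothing.
    """
    if min_offsite_frames <= 1:
        return visits

    def is_site(tok) -> bool:
        return isinstance(tok, (int, np.integer))

    out: list[tuple[int, int | str]] = []
    for k, ((fr, tok), n) in enumerate(zip(visits, frame_counts)):
        grazing = (
            not is_site(tok)
            and n < min_offsite_frames
            and 0 < k < len(visits) - 1
            and is_site(visits[k - 1][1])
            and is_site(visits[k + 1][1])
        )
        if grazing:
            continue
        if out and out[-1][1] == tok:
            continue
        out.append((fr, tok))
    return out


def ion_itineraries(
    ion_sites: pd.DataFrame,
    model: SiteModel,
    min_offsite_frames: int = 1,
) -> list[IonItinerary]:
    """Per-ion collapsed site itineraries.

    ``ion_sites`` is the long-form table produced by
    :func:`~porestate.site_model.discretize_trajectory` (attrs['ion_sites']):
    columns frame, ion_id, z_A, site.  Ions that never occupy a site are
    excluded.
    """
    its: list[IonItinerary] = []
    for ion_id, g in ion_sites.groupby("ion_id", sort=True):
        g = g.sort_values("frame", kind="stable")
        sites = g["site"].to_numpy()
        if not (sites != NONE_SITE).any():
            continue
        visits = _tokenize_ion(
            g["frame"].to_numpy(), sites, g["z_A"].to_numpy(), model
        )
        if min_offsite_frames > 1:
            frames = [fr for fr, _ in visits] + [int(g["frame"].iloc[-1]) + 1]
            counts = [b - a for a, b in zip(frames, frames[1:])]
            visits = _smooth_grazing(visits, counts, min_offsite_frames)
        its.append(IonItinerary(ion_id=int(ion_id), visits=visits))
    return its


def count_permeations(itineraries: Sequence[IonItinerary]) -> tuple[int, int]:
    """(outward, inward) full crossings over all itineraries.

    Outward = entered from the intracellular reservoir, visited at least
    one site, exited to the extracellular reservoir; inward is symmetric.
    A crossing requires both reservoir visits to be witnessed; ions already
    in the pore at the start of the record have no entry side and their
    first exit counts nothing.
    """
    outward = inward = 0
    for it in itineraries:
        entry_side: str | None = None
        seen_site = False
        for tok in it.tokens():
            if isinstance(tok, (int, np.integer)):
                seen_site = True
            elif tok in (EXTRA, INTRA):
                if seen_site and entry_side is not None and tok != entry_side:
                    if entry_side == INTRA:
                        outward += 1
                    else:
                        inward += 1
                entry_side = tok
                seen_site = False
            # OFFSITE: neither resets nor completes a crossing
    return outward, inward


def write_itineraries(itineraries: Sequence[IonItinerary], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("ion_id\tfirst_frame\ttoken\n")
        for it in itineraries:
            for fr, tok in it.visits:
                name = f"S{tok}" if isinstance(tok, (int, np.integer)) else str(tok)
                fh.write(f"{it.ion_id}\t{fr}\t{name}\n")
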