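"""Seeded synthetic trajectories of single-file ion hopping.

The generator emulates the phenomenology of K+-channel permeation that the
pipeline is designed to analyze — several ions held at discrete sites on a
straight pore axis, hopping stochastically between adjacent sites with
hard-core exclusion, entering from one reservoir and leaving by the other —
without any physics (no electrostatics, water or force field).  It is a
combinatorial surrogate whose every frame carries ground-truth labels, so
each pipeline stage can be checked exactly.

Dynamics are a discrete-time Markov chain at the frame interval: in each
step at most one move fires, chosen categorically with probability
rate × dt (nothing happens with the remaining probability).  This keeps the
embedded occupancy chain's one-frame transition matrix exactly computable
(2^n_sites states), which the stationary-distribution oracles rely on; the
guard ``sum(rate × dt) > 0.5`` rejects time steps too coarse for the
single-event approximation.

Geometry: two static rings of four basis atoms define the pore axis along
+z (extracellular up); pore ions sit at their site center plus isotropic
Gaussian noise, reservoir ions in slabs beyond the terminal boundaries.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .site_model import SiteModel
from .trajectory_io import Frame, Selections, make_topology, write_plaintext

__all__ = [
    "HoppingModel",
    "GroundTruth",
    "simulate",
    "seven_site_model",
    "kv12_like_model",
    "two_mechanism_events",
    "make_fixture_suite",
    "PRESETS",
]

_RES_OFFSET = 5.0  # Å between a terminal boundary and its reservoir slab


@dataclass(frozen=True)
class HoppingModel:
    """Kinetic model of single-file hopping through a linear pore.

    Rates are in 1/ps; ``dt`` (ps) is the frame interval, so each move's
    per-frame probability is rate × dt.  ``hop_up`` moves an ion toward the
    extracellular side (site i → i−1), ``hop_down`` the reverse.  Entry and
    exit default to the outward direction (intracellular entry at the last
    site, extracellular exit from site 0); the reverse pair is optional.
    """

    site_centers: tuple[float, ...]  # Å, strictly descending
    hop_up: float = 0.0
    hop_down: float = 0.0
    entry_rate: float = 0.0  # intra reservoir -> site n-1
    exit_rate: float = 0.0  # site 0 -> extra reservoir
    entry_rate_extra: float = 0.0  # extra reservoir -> site 0
    exit_rate_intra: float = 0.0  # site n-1 -> intra reservoir
    exclusion: bool = True
    # minimum site-index separation between ions: 1 = hard-core exclusion
    # only, 2 = no adjacent occupancy (mutual repulsion, water-separated
    # ions as in a K+ selectivity filter)
    min_separation: int = 1
    sigma: float = 0.0  # Å, isotropic positional noise
    dt: float = 10.0  # ps per frame
    species: str = "K"
    initial_sites: tuple[int, ...] = ()
    n_reservoir_ions: int = 20
    recycle_ids: bool = False
    boundaries: tuple[float, ...] | None = None  # explicit override

    def __post_init__(self) -> None:
        c = tuple(float(x) for x in self.site_centers)
        if len(c) < 2 or any(hi <= lo for hi, lo in zip(c, c[1:])):
            raise ValueError("site centers must be strictly descending, >= 2 sites")
        object.__setattr__(self, "site_centers", c)
        for name in ("hop_up", "hop_down", "entry_rate", "exit_rate",
                     "entry_rate_extra", "exit_rate_intra"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.min_separation < 1:
            raise ValueError("min_separation must be >= 1")
        if len(set(self.initial_sites)) != len(self.initial_sites):
            raise ValueError("initial_sites must be distinct under exclusion")
        init = sorted(self.initial_sites)
        if any(b - a < self.min_separation for a, b in zip(init, init[1:])):
            raise ValueError("initial_sites violate min_separation")

    @property
    def n_sites(self) -> int:
        return len(self.site_centers)

    def site_boundaries(self) -> tuple[float, ...]:
        """Boundary list: explicit override or midpoints, extended outward."""
        if self.boundaries is not None:
            return tuple(self.boundaries)
        c = np.asarray(self.site_centers)
        mids = 0.5 * (c[:-1] + c[1:])
        top = c[0] + 0.5 * (c[0] - c[1])
        bottom = c[-1] - 0.5 * (c[-2] - c[-1])
        return tuple([top, *mids, bottom])

    def site_model(self) -> SiteModel:
        return SiteModel(boundaries=self.site_boundaries(), species_label=self.species)

    # --- geometry -------------------------------------------------------

    def basis_positions(self) -> tuple[np.ndarray, np.ndarray]:
        """Two static 4-atom rings centered on (0,0,0) and (0,0,5)."""
        ring = np.array([[3.0, 0, 0], [0, 3.0, 0], [-3.0, 0, 0], [0, -3.0, 0]])
        return ring + [0, 0, 0.0], ring + [0, 0, 5.0]

    @property
    def n_ions(self) -> int:
        return len(self.initial_sites) + self.n_reservoir_ions

    def topology(self) -> pd.DataFrame:
        names = ["O"] * 8 + [self.species] * self.n_ions
        resids = [374] * 4 + [377] * 4 + [1000 + i for i in range(self.n_ions)]
        resnames = ["THR"] * 4 + ["TYR"] * 4 + [self.species] * self.n_ions
        return make_topology(names, resids, resnames)

    def selections(self) -> Selections:
        return Selections(
            basis_from=list(range(4)),
            basis_to=list(range(4, 8)),
            ions=list(range(8, 8 + self.n_ions)),
            species_label=self.species,
        )


@dataclass
class GroundTruth:
    """Per-frame labels and event log emitted alongside a simulation."""

    model: HoppingModel
    state_labels: list[str]
    hop_log: list[tuple[int, int, int | str, int | str]]  # frame, ion, from, to
    outward_permeations: int
    inward_permeations: int
    min_intra_reservoir: int
    entry_always_available: bool = True

    def occupancy_states(self) -> list[frozenset[int]]:
        states = []
        for i in range(2 ** self.model.n_sites):
            states.append(frozenset(k for k in range(self.model.n_sites) if i >> k & 1))
        return states

    def transition_matrix(self) -> tuple[list[frozenset[int]], np.ndarray]:
        """Exact one-frame transition matrix of the occupancy chain.

        Built over the occupancies reachable from the initial one (BFS over
        legal moves), assuming the intracellular reservoir never runs dry
        (checked on the simulated run via ``min_intra_reservoir``).
        """
        m = self.model
        start = frozenset(m.initial_sites)
        seen = {start}
        order = [start]
        k = 0
        while k < len(order):
            s = order[k]
            k += 1
            for s_next, _ in _legal_occupancy_moves(m, s):
                if s_next not in seen:
                    seen.add(s_next)
                    order.append(s_next)
        index = {s: i for i, s in enumerate(order)}
        P = np.zeros((len(order), len(order)))
        for s in order:
            total = 0.0
            for s_next, p in _legal_occupancy_moves(m, s):
                P[index[s], index[s_next]] += p
                total += p
            P[index[s], index[s]] += 1.0 - total
        return order, P

    def stationary_distribution(self) -> dict[str, float]:
        """Stationary state-label probabilities of the occupancy chain.

        Restricted to the communicating class reachable from the initial
        occupancy (anything else has probability 0).
        """
        states, P = self.transition_matrix()
        n = len(states)
        A = np.vstack([P.T - np.eye(n), np.ones(n)])
        b = np.zeros(n + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        pi = np.clip(pi, 0, None)
        pi /= pi.sum()
        out: dict[str, float] = {}
        for s, p in zip(states, pi):
            label = self.model.species + ":" + ":".join(str(k) for k in sorted(s))
            out[label] = out.get(label, 0.0) + float(p)
        return out

    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        with open(f"{prefix}.truth_states.tsv", "w") as fh:
            fh.write("frame\ttrue_state\n")
            for i, s in enumerate(self.state_labels):
                fh.write(f"{i}\t{s}\n")
        with open(f"{prefix}.hops.tsv", "w") as fh:
            fh.write("frame\tion_id\tfrom_site\tto_site\n")
            for fr, ion, a, b in self.hop_log:
                fh.write(f"{fr}\t{ion}\t{a}\t{b}\n")
        with open(f"{prefix}.permeations.tsv", "w") as fh:
            fh.write("outward\tinward\n")
            fh.write(f"{self.outward_permeations}\t{self.inward_permeations}\n")


def _site_free(m: HoppingModel, occ, target: int, source: int | None = None) -> bool:
    """True if ``target`` and its min_separation neighborhood are free.

    ``source`` is the site the moving ion leaves (ignored in the check).
    """
    lo = max(0, target - m.min_separation + 1)
    hi = min(m.n_sites - 1, target + m.min_separation - 1)
    return all(j == source or j not in occ for j in range(lo, hi + 1))


def _legal_occupancy_moves(
    m: HoppingModel, occ: frozenset[int]
) -> list[tuple[frozenset[int], float]]:
    """(next occupancy, probability) pairs for one chain step (exclusion on)."""
    n = m.n_sites
    dt = m.dt
    moves: list[tuple[frozenset[int], float]] = []
    for i in occ:
        if m.hop_up > 0 and i > 0 and _site_free(m, occ, i - 1, source=i):
            moves.append((occ - {i} | {i - 1}, m.hop_up * dt))
        if m.hop_down > 0 and i < n - 1 and _site_free(m, occ, i + 1, source=i):
            moves.append((occ - {i} | {i + 1}, m.hop_down * dt))
    if m.exit_rate > 0 and 0 in occ:
        moves.append((occ - {0}, m.exit_rate * dt))
    if m.exit_rate_intra > 0 and (n - 1) in occ:
        moves.append((occ - {n - 1}, m.exit_rate_intra * dt))
    if m.entry_rate > 0 and _site_free(m, occ, n - 1):
        moves.append((occ | {n - 1}, m.entry_rate * dt))
    if m.entry_rate_extra > 0 and _site_free(m, occ, 0):
        moves.append((occ | {0}, m.entry_rate_extra * dt))
    return moves


def simulate(
    model: HoppingModel, n_frames: int, seed: int
) -> tuple[list[Frame], GroundTruth]:
    """Run the hopping chain and emit coordinate frames + ground truth.

    Frame 0 is the initial configuration; each later frame follows one
    chain step.  Fully reproducible from ``seed``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    m = model
    rng = np.random.default_rng(seed)
    n = m.n_sites
    basis_from, basis_to = m.basis_positions()
    basis = np.vstack([basis_from, basis_to])
    bounds = m.site_boundaries()
    slab_z = {"intra": bounds[-1] - _RES_OFFSET, "extra": bounds[0] + _RES_OFFSET}

    # ion bookkeeping: location is ("site", i) or ("res", side)
    n_ions = m.n_ions
    loc: list[tuple[str, object]] = []
    site_of: dict[int, int] = {}
    for k, s in enumerate(m.initial_sites):
        if not 0 <= s < n:
            raise ValueError(f"initial site {s} out of range")
        loc.append(("site", s))
        site_of[s] = k
    intra_queue = list(range(len(m.initial_sites), n_ions))
    extra_queue: list[int] = []
    for _ in intra_queue:
        loc.append(("res", "intra"))
    entry_side: list[str | None] = [None] * n_ions
    lateral = np.array(
        [[2.0 * (i % 5 - 2), 2.0 * (i // 5 % 5 - 2), 0.0] for i in range(n_ions)]
    )

    frames: list[Frame] = []
    labels: list[str] = []
    hop_log: list[tuple[int, int, int | str, int | str]] = []
    outward = inward = 0
    min_intra = len(intra_queue)

    def record(frame_idx: int) -> None:
        pos = np.empty((8 + n_ions, 3))
        pos[:8] = basis
        for ion in range(n_ions):
            kind, where = loc[ion]
            if kind == "site":
                center = np.array([0.0, 0.0, m.site_centers[int(where)]])
            else:
                center = lateral[ion] + [0.0, 0.0, slab_z[str(where)]]
            noise = rng.normal(0.0, m.sigma, 3) if m.sigma > 0 else 0.0
            pos[8 + ion] = center + noise
        frames.append(Frame(index=frame_idx, time=frame_idx * m.dt, positions=pos))
        occ = sorted(site_of)
        labels.append(m.species + ":" + ":".join(str(s) for s in occ))

    entry_starved = 0
    record(0)
    for t in range(1, n_frames):
        if m.recycle_ids and not intra_queue and extra_queue:
            ion = extra_queue.pop(0)
            loc[ion] = ("res", "intra")
            entry_side[ion] = None
            intra_queue.append(ion)
        # availability is what matters at the moment moves are drawn
        min_intra = min(min_intra, len(intra_queue))
        if m.entry_rate > 0 and not intra_queue:
            entry_starved += 1
        # enumerate legal moves: (prob, kind, payload)
        moves: list[tuple[float, str, tuple]] = []
        for s, ion in site_of.items():
            if m.hop_up > 0 and s > 0 and _site_free(m, site_of, s - 1, source=s):
                moves.append((m.hop_up * m.dt, "hop", (ion, s, s - 1)))
            if m.hop_down > 0 and s < n - 1 and _site_free(m, site_of, s + 1, source=s):
                moves.append((m.hop_down * m.dt, "hop", (ion, s, s + 1)))
        if m.exit_rate > 0 and 0 in site_of:
            moves.append((m.exit_rate * m.dt, "exit", (site_of[0], 0, "extra")))
        if m.exit_rate_intra > 0 and (n - 1) in site_of:
            moves.append(
                (m.exit_rate_intra * m.dt, "exit", (site_of[n - 1], n - 1, "intra"))
            )
        if m.entry_rate > 0 and _site_free(m, site_of, n - 1) and intra_queue:
            moves.append((m.entry_rate * m.dt, "entry", ("intra", n - 1)))
        if m.entry_rate_extra > 0 and _site_free(m, site_of, 0) and extra_queue:
            moves.append((m.entry_rate_extra * m.dt, "entry", ("extra", 0)))
        total = sum(p for p, _, _ in moves)
        if total > 0.5:
            raise ValueError(
                f"sum of move probabilities {total:.3f} > 0.5: time step too "
                "coarse for single-event stepping (reduce rates or dt)"
            )
        u = rng.random()
        acc = 0.0
        chosen = None
        for p, kind, payload in moves:
            acc += p
            if u < acc:
                chosen = (kind, payload)
                break
        if chosen is not None:
            kind, payload = chosen
            if kind == "hop":
                ion, a, b = payload
                del site_of[a]
                site_of[b] = ion
                loc[ion] = ("site", b)
                hop_log.append((t, ion, a, b))
            elif kind == "exit":
                ion, a, side = payload
                del site_of[a]
                loc[ion] = ("res", side)
                (extra_queue if side == "extra" else intra_queue).append(ion)
                hop_log.append((t, ion, a, side))
                if entry_side[ion] == "intra" and side == "extra":
                    outward += 1
                elif entry_side[ion] == "extra" and side == "intra":
                    inward += 1
                entry_side[ion] = None
            else:  # entry
                side, s = payload
                queue = intra_queue if side == "intra" else extra_queue
                ion = queue.pop(0)
                site_of[s] = ion
                loc[ion] = ("site", s)
                entry_side[ion] = side
                hop_log.append((t, ion, side, s))
        record(t)

    truth = GroundTruth(
        model=m,
        state_labels=labels,
        hop_log=hop_log,
        outward_permeations=outward,
        inward_permeations=inward,
        min_intra_reservoir=min_intra,
        entry_always_available=(entry_starved == 0),
    )
    return frames, truth


# ---------------------------------------------------------------------------
# stock geometries
# ---------------------------------------------------------------------------


def seven_site_model(**overrides) -> HoppingModel:
    """Seven sites at 4 Å spacing (z = +12 … −12), three ions at S0/S2/S4.

    The 4 Å spacing keeps the site half-gap at 4 sigma for the default
    noise of 0.5 Å, so state discretization is essentially error-free.
    """
    defaults = dict(
        site_centers=(12.0, 8.0, 4.0, 0.0, -4.0, -8.0, -12.0),
        # strongly outward-biased rates, emulating a driven (voltage-held)
        # channel: conduction proceeds as entry -> upward march -> exit
        hop_up=0.004,
        hop_down=0.0005,
        entry_rate=0.004,
        exit_rate=0.006,
        min_separation=2,
        sigma=0.5,
        dt=10.0,
        initial_sites=(0, 2, 4),
        n_reservoir_ions=20,
        recycle_ids=True,
    )
    defaults.update(overrides)
    return HoppingModel(**defaults)


def kv12_like_model(**overrides) -> HoppingModel:
    """Seven-site geometry with a Kv1.2-style boundary list.

    Boundaries 12.93, 9.32, 6.25, 3.00, 0.44, −2.21, −6.08, −20 Å (S6 is
    the wide central cavity below the selectivity filter); site centers at
    the interval midpoints.
    """
    bounds = (12.93, 9.32, 6.25, 3.00, 0.44, -2.21, -6.08, -20.0)
    centers = tuple(0.5 * (a + b) for a, b in zip(bounds, bounds[1:]))
    defaults = dict(
        site_centers=centers,
        boundaries=bounds,
        hop_up=0.004,
        hop_down=0.0005,
        entry_rate=0.004,
        exit_rate=0.006,
        min_separation=2,
        sigma=0.4,
        dt=10.0,
        initial_sites=(0, 2, 4),
        n_reservoir_ions=20,
        recycle_ids=True,
    )
    defaults.update(overrides)
    return HoppingModel(**defaults)


# ---------------------------------------------------------------------------
# two-mechanism event templates
# ---------------------------------------------------------------------------

_ANCHOR = "K:0:2:4"
# concerted knock-on: the incoming ion pushes the file, the outermost leaves
_KNOCKON = [_ANCHOR, "K:0:2:4:6", "K:0:2:4:5", "K:2:4:5", "K:1:3:5", _ANCHOR]
# association/dissociation: an ion leaves first, another binds later
_AD = [_ANCHOR, "K:2:4", "K:1:4", "K:1:4:6", "K:1:3:6", _ANCHOR]
_SUB_POOLS = {
    2: ["K:2:4", "K:1:4", "K:2:5", "K:3:5"],
    3: ["K:1:3:5", "K:2:4:5", "K:1:2:4", "K:0:3:5", "K:2:3:5", "K:1:3:6"],
    4: ["K:0:2:4:6", "K:0:2:4:5", "K:1:3:4:6", "K:0:1:3:5"],
}


def two_mechanism_events(
    n_events: int, seed: int, p_sub: float = 0.25, p_del: float = 0.15
) -> tuple[list[list[str]], list[int]]:
    """Event state-sequences drawn from two mechanism templates.

    Half the events follow a knock-on-like state ordering, half an
    association/dissociation-like one; interior states are perturbed by
    same-ion-count substitutions (prob ``p_sub`` per position) and
    occasional deletions (``p_del``), emulating the within-mechanism
    variability seen in real event sets.  Returns (events, template ids).
    """
    rng = np.random.default_rng(seed)
    events: list[list[str]] = []
    ids: list[int] = []
    from .site_model import state_ion_count

    for k in range(n_events):
        tid = k % 2
        template = _KNOCKON if tid == 0 else _AD
        seq = list(template)
        interior = list(range(1, len(seq) - 1))
        for i in interior:
            if rng.random() < p_sub:
                pool = [
                    s
                    for s in _SUB_POOLS[state_ion_count(seq[i])]
                    if s != seq[i] and s != seq[i - 1]
                ]
                if pool:
                    seq[i] = pool[rng.integers(len(pool))]
        if len(seq) > 4 and rng.random() < p_del:
            i = int(rng.choice(interior[1:-1]))
            if seq[i - 1] != seq[i + 1]:
                del seq[i]
        # collapse accidental adjacent duplicates
        seq = [s for j, s in enumerate(seq) if j == 0 or s != seq[j - 1]]
        events.append(seq)
        ids.append(tid)
    return events, ids


# ---------------------------------------------------------------------------
# fixture suite
# ---------------------------------------------------------------------------


def _build_static_024(outdir: Path, seed: int) -> dict:
    model = seven_site_model(
        hop_up=0.0, hop_down=0.0, entry_rate=0.0, exit_rate=0.0, sigma=0.0,
        n_reservoir_ions=2, recycle_ids=False,
    )
    frames, truth = simulate(model, 100, seed)
    return {"model": model, "frames": frames, "truth": truth}


def _build_knockon_bias(outdir: Path, seed: int) -> dict:
    model = seven_site_model(hop_up=0.008, hop_down=0.0, entry_rate=0.008,
                             exit_rate=0.01)
    frames, truth = simulate(model, 20_000, seed)
    return {"model": model, "frames": frames, "truth": truth}


def _build_kv12_like(outdir: Path, seed: int) -> dict:
    model = kv12_like_model()
    frames, truth = simulate(model, 20_000, seed)
    return {"model": model, "frames": frames, "truth": truth}


def _build_two_mechanisms(outdir: Path, seed: int) -> dict:
    events, ids = two_mechanism_events(16, seed)
    return {"events": events, "template_ids": ids}


PRESETS = {
    "static_024": _build_static_024,
    "knockon_bias": _build_knockon_bias,
    "kv12_like_7site": _build_kv12_like,
    "two_mechanisms": _build_two_mechanisms,
}


def _write_config(path: Path, model: HoppingModel, traj_path: Path, seed: int) -> None:
    bounds = ", ".join(f"{b:g}" for b in model.site_boundaries())
    path.write_text(
        f"fn-trr = {traj_path.name}\n"
        f"fn-topology = {traj_path.name.replace('.traj.txt', '.topology.tsv')}\n"
        f"trajectory-format = plaintext\n"
        f"pore-axis-basis-from = resid 374 and name O\n"
        f"pore-axis-basis-to = resid 377 and name O\n"
        f"ion-selection = name {model.species}\n"
        f"species-label = {model.species}\n"
        f"site-boundary = {bounds}\n"
        f"seed = {seed}\n"
    )


def make_fixture_suite(
    presets: Sequence[str], outdir: str | Path, seed: int = 0
) -> dict[str, dict]:
    """Materialize named presets as plaintext trajectories + sidecars.

    Each preset writes ``<name>.traj.txt``, ``<name>.config`` and
    ground-truth TSVs (or ``<name>.events.tsv`` for the template preset).
    Returns the in-memory objects per preset.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out: dict[str, dict] = {}
    for name in presets:
        if name not in PRESETS:
            raise KeyError(
                f"unknown preset {name!r}; available: {sorted(PRESETS)}"
            )
        # derive a per-preset subseed so presets are independent of ordering
        sub = int.from_bytes(
            hashlib.sha256(f"{seed}:{name}".encode()).digest()[:4], "big"
        ) % (2**31)
        built = PRESETS[name](outdir, sub)
        prefix = outdir / name
        if "frames" in built:
            traj = Path(f"{prefix}.traj.txt")
            write_plaintext(built["frames"], traj)
            built["truth"].write(prefix)
            built["model"].topology().to_csv(
                f"{prefix}.topology.tsv", sep="\t", index=False
            )
            _write_config(Path(f"{prefix}.config"), built["model"], traj, sub)
        else:
            with open(f"{prefix}.events.tsv", "w") as fh:
                fh.write("event_id\ttemplate\tstates\n")
                for i, (ev, tid) in enumerate(
                    zip(built["events"], built["template_ids"])
                ):
                    fh.write(f"{i}\t{tid}\t{','.join(ev)}\n")
        out[name] = built
    return out
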