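"""Synthetic paired homing flights with known ground-truth coupling.

The generator emulates the transmission-chain release design: two birds fly
5 Hz tracks with persistent headings and home-directed drift; at each step
one bird is the latent *leader* and steers (blending its previous heading
with the bearing to home, or to an off-route waypoint during an exploration
bout), while the *follower* blends its own persistence, the leader's
heading a delay ``tau`` steps earlier, and attraction towards the partner
when the pair opens up beyond a cohesion radius.  Leader identity flips as
a first-order Markov chain (geometric run lengths), or, in the
``duration_mode='lognormal'`` variant, with log-normally distributed run
lengths.  Heading blending uses the normalised weighted sum of unit
vectors, never raw angle averaging, to avoid wrap-around artefacts.

Every flight draws all randomness from a single :class:`numpy.random
.Generator` seeded per flight, so runs reproduce bit-for-bit.

Ground truth records, per step, the latent leader, whether the bird (pair)
is farther than the 300 m labelling threshold from the ideal release–home
corridor (``explore_state``), and the mechanistic in-bout flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError
from .io import PairFlight, Trajectory

__all__ = ["SimConfig", "GroundTruth", "ChainFlight", "simulate_pair_flight",
           "simulate_solo_flight", "simulate_transmission_chain",
           "generate_binary_channel"]

EXPLORE_THRESHOLD_M = 300.0     # labelling threshold the bouts must cross


@dataclass
class SimConfig:
    """Parameters of one simulated paired flight.

    All heading weights live on a convex blend: the follower mixes its own
    previous heading (weight ``1 − w_couple − alpha_attract``), the
    partner's heading ``tau`` steps earlier (``w_couple``) and the bearing
    to the partner when separation exceeds ``r_coh`` (``alpha_attract``);
    the leader mixes its previous heading with the bearing to its current
    goal (``beta_home``).  Ground speed defaults to 20 m/s, a conventional
    homing-pigeon cruise speed.
    """

    n_steps: int = 2600               # ~8.7 min at 5 Hz
    dt: float = 0.2                   # seconds per step
    speed: float = 20.0               # metres / second
    w_couple: float = 0.6             # follower: weight on leader's past heading
    tau: int = 1                      # coupling delay, steps
    alpha_attract: float = 0.25       # follower: weight on bearing-to-partner
    r_coh: float = 10.0               # cohesion radius, metres
    beta_home: float = 0.2            # leader: weight on bearing-to-goal
    sigma_heading: float = 0.12       # heading noise SD, radians/step
    q_switch: float = 0.005           # per-step leader-switch probability
    p_explore: float = 0.0            # per-step bout-start probability
    explore_band: tuple = (300.0, 1000.0)   # lateral waypoint band, metres
    max_bout_steps: int = 600
    duration_mode: str = "markov"     # or 'lognormal'
    lognorm_mu: float = 4.0           # log-mean of run length (steps)
    lognorm_sigma: float = 0.8
    explore_leader: str | None = None  # force 'E'/'N' to lead bouts
    release: tuple = (0.0, 0.0)
    home: tuple = (8000.0, 0.0)
    stop_at_home: bool = False        # truncate on arrival within arrival_radius
    arrival_radius: float = 200.0
    seed: int = 0

    def validate(self) -> None:
        if self.dt <= 0 or self.speed <= 0:
            raise ConfigurationError("dt and speed must be positive")
        if self.tau < 1:
            raise ConfigurationError("coupling delay tau must be >= 1")
        if self.n_steps <= self.tau:
            raise ConfigurationError("n_steps must exceed tau")
        for name in ("w_couple", "alpha_attract", "beta_home",
                     "q_switch", "p_explore"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.w_couple + self.alpha_attract > 1.0 + 1e-12:
            raise ConfigurationError(
                "w_couple + alpha_attract must not exceed 1 (convex blend)")
        if self.duration_mode not in ("markov", "lognormal"):
            raise ConfigurationError("duration_mode must be 'markov' or 'lognormal'")
        if self.explore_leader not in (None, "E", "N"):
            raise ConfigurationError("explore_leader must be None, 'E' or 'N'")


@dataclass
class GroundTruth:
    """Latent per-step state of a simulated flight."""

    leader_state: np.ndarray      # 'E'/'N' per step
    explore_state: np.ndarray     # bool: > 300 m from the ideal corridor
    in_bout: np.ndarray           # bool: mechanistic bout flag
    w_couple: float
    tau: int

    def leader_run_lengths(self) -> np.ndarray:
        """Lengths (steps) of maximal constant-leader runs."""
        s = self.leader_state
        change = np.nonzero(s[1:] != s[:-1])[0] + 1
        edges = np.concatenate(([0], change, [len(s)]))
        return np.diff(edges)


@dataclass
class ChainFlight:
    """One release of a transmission chain: a pair or a solo flight."""

    chain_id: str
    generation: int
    release: int
    pair: PairFlight | None
    solo: Trajectory | None
    ground_truth: GroundTruth

    @property
    def is_solo(self) -> bool:
        return self.pair is None


def _blend(components) -> float:
    """Angle of the normalised weighted sum of unit vectors."""
    x = sum(w * math.cos(a) for w, a in components)
    y = sum(w * math.sin(a) for w, a in components)
    if x == 0.0 and y == 0.0:
        return components[0][1]
    return math.atan2(y, x)


def _point_segment_distance(px, py, ax, ay, bx, by) -> float:
    vx, vy = bx - ax, by - ay
    t = ((px - ax) * vx + (py - ay) * vy) / (vx * vx + vy * vy)
    t = min(1.0, max(0.0, t))
    return math.hypot(px - (ax + t * vx), py - (ay + t * vy))


def _draw_run_length(cfg: SimConfig, rng) -> int:
    if cfg.duration_mode == "lognormal":
        return max(1, int(round(rng.lognormal(cfg.lognorm_mu, cfg.lognorm_sigma))))
    if cfg.q_switch <= 0:
        return cfg.n_steps + 1
    return int(rng.geometric(cfg.q_switch))


def simulate_pair_flight(config: SimConfig,
                         bird_ids: tuple[str, str] = ("E", "N"),
                         metadata: tuple = ("sim", 2, 1),
                         ) -> tuple[PairFlight, GroundTruth]:
    """Simulate one paired release; returns the flight and its ground truth.

    ``bird_ids`` name the experienced- and naive-role birds; ``metadata``
    is ``(chain_id, generation, release)``.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_steps
    step_len = cfg.speed * cfg.dt
    hx, hy = cfg.home
    rx, ry = cfg.release

    home_bearing = math.atan2(hy - ry, hx - rx)
    # positions: E starts a few metres left of the release point, N right
    off = 4.0
    perp = home_bearing + math.pi / 2
    pos = np.empty((2, n, 2))
    pos[0, 0] = (rx + off * math.cos(perp), ry + off * math.sin(perp))
    pos[1, 0] = (rx - off * math.cos(perp), ry - off * math.sin(perp))
    heading = np.empty((2, n))
    heading[:, 0] = home_bearing

    leader = np.empty(n, dtype="<U1")
    in_bout = np.zeros(n, dtype=bool)
    explore = np.zeros(n, dtype=bool)

    noise = rng.normal(0.0, cfg.sigma_heading, size=(2, n))
    u_switch = rng.random(n)
    u_bout = rng.random(n)

    if cfg.duration_mode == "markov" and cfg.q_switch == 0.0:
        cur_leader = 0          # no switching: the experienced slot leads
    else:
        cur_leader = 0 if rng.random() < 0.5 else 1   # index: 0 = E, 1 = N
    run_left = _draw_run_length(cfg, rng)
    bout_left = 0
    bout_goal = (hx, hy)
    bout_phase = 0   # 0 none, 1 outbound, 2 re-entry

    forced = {"E": 0, "N": 1}.get(cfg.explore_leader or "", None)

    leader[0] = "E" if cur_leader == 0 else "N"
    for i in range(1, n):
        # latent leader dynamics
        if cfg.duration_mode == "markov":
            if u_switch[i] < cfg.q_switch and not (bout_phase and forced is not None):
                cur_leader = 1 - cur_leader
        else:
            run_left -= 1
            if run_left <= 0 and not (bout_phase and forced is not None):
                cur_leader = 1 - cur_leader
                run_left = _draw_run_length(cfg, rng)

        # exploration bout state machine (driven by the leader's goal):
        # dart out to a waypoint lateral to the current along-track position,
        # then cut back to the corridor a little ahead
        lead_pos = pos[cur_leader, i - 1]
        corridor_len = math.hypot(hx - rx, hy - ry)
        ux, uy = (hx - rx) / corridor_len, (hy - ry) / corridor_len
        along = min(max(((lead_pos[0] - rx) * ux + (lead_pos[1] - ry) * uy),
                        0.0), corridor_len)
        if bout_phase == 0 and cfg.p_explore > 0 and u_bout[i] < cfg.p_explore:
            lo, hi = cfg.explore_band
            lateral = rng.uniform(lo, hi) * (1 if rng.random() < 0.5 else -1)
            fwd = min(along + rng.uniform(0.0, 150.0), corridor_len)
            bout_goal = (rx + fwd * ux + lateral * math.cos(perp),
                         ry + fwd * uy + lateral * math.sin(perp))
            bout_phase = 1
            bout_left = cfg.max_bout_steps
            if forced is not None:
                cur_leader = forced
        if bout_phase == 1:
            if math.hypot(lead_pos[0] - bout_goal[0],
                          lead_pos[1] - bout_goal[1]) < 100.0 or bout_left <= 0:
                bout_phase = 2
        if bout_phase == 2:
            fwd = min(along + 150.0, corridor_len)
            bout_goal = (rx + fwd * ux, ry + fwd * uy)
            corr_d = _point_segment_distance(lead_pos[0], lead_pos[1],
                                             rx, ry, hx, hy)
            if corr_d < 150.0 or bout_left <= -cfg.max_bout_steps:
                bout_phase = 0
        bout_left -= 1

        for b in (0, 1):
            prev = heading[b, i - 1]
            px, py = pos[b, i - 1]
            if b == cur_leader:
                if bout_phase:
                    gx, gy = bout_goal   # outbound waypoint, then re-entry point
                else:
                    gx, gy = hx, hy
                goal = math.atan2(gy - py, gx - px)
                ang = _blend([(1.0 - cfg.beta_home, prev), (cfg.beta_home, goal)])
            else:
                partner_past = heading[1 - b, max(i - cfg.tau, 0)]
                ox, oy = pos[1 - b, i - 1]
                sep = math.hypot(ox - px, oy - py)
                comps = [(1.0 - cfg.w_couple - cfg.alpha_attract, prev),
                         (cfg.w_couple, partner_past)]
                if sep > cfg.r_coh:
                    comps.append((cfg.alpha_attract,
                                  math.atan2(oy - py, ox - px)))
                else:
                    comps[0] = (comps[0][0] + cfg.alpha_attract, prev)
                ang = _blend(comps)
            ang += noise[b, i]
            heading[b, i] = ang
            pos[b, i] = (px + step_len * math.cos(ang),
                         py + step_len * math.sin(ang))

        leader[i] = "E" if cur_leader == 0 else "N"
        in_bout[i] = bout_phase != 0

    if cfg.stop_at_home:
        # tracks end on arrival at the loft, as real GPS tracks do; the
        # steering slot's position decides (robust to a ghost partner)
        lead_d = np.hypot(pos[0, :, 0] - hx, pos[0, :, 1] - hy)
        arrived = np.nonzero(lead_d < cfg.arrival_radius)[0]
        if len(arrived) and arrived[0] > cfg.tau + 2:
            n = int(arrived[0]) + 1
            pos = pos[:, :n]
            leader = leader[:n]
            in_bout = in_bout[:n]

    # geometric ground truth: pair midpoint beyond 300 m of the corridor
    mid = pos.mean(axis=0)
    explore = np.array([
        _point_segment_distance(x, y, rx, ry, hx, hy) > EXPLORE_THRESHOLD_M
        for x, y in mid])

    t = cfg.dt * np.arange(n)
    chain_id, generation, release = metadata
    tr_e = Trajectory(bird_ids[0], chain_id, generation, release, t, pos[0])
    tr_n = Trajectory(bird_ids[1], chain_id, generation, release,
                      t.copy(), pos[1])
    pf = PairFlight(experienced=tr_e, naive=tr_n, chain_id=chain_id,
                    generation=generation, release=release)
    gt = GroundTruth(leader_state=leader, explore_state=explore,
                     in_bout=in_bout, w_couple=cfg.w_couple, tau=cfg.tau)
    return pf, gt


def simulate_solo_flight(config: SimConfig, bird_id: str = "S",
                         metadata: tuple = ("sim", 1, 1)) -> tuple[Trajectory, GroundTruth]:
    """One single-bird release: the leader rule only, no partner."""
    # a single steering bird: no coupling, and the latent leader never flips
    # to the unused ghost slot
    solo_cfg = replace(config, w_couple=0.0, alpha_attract=0.0,
                       q_switch=0.0, duration_mode="markov",
                       explore_leader=None)
    pf, gt = simulate_pair_flight(solo_cfg, bird_ids=(bird_id, "_ghost"),
                                  metadata=metadata)
    # keep only the steering bird's track; its own positions (not the pair
    # midpoint) define the geometric exploration ground truth
    rx, ry = config.release
    hx, hy = config.home
    explore = np.array([
        _point_segment_distance(x, y, rx, ry, hx, hy) > EXPLORE_THRESHOLD_M
        for x, y in pf.experienced.xy])
    gt = GroundTruth(leader_state=np.full(len(pf.experienced), "E", dtype="<U1"),
                     explore_state=explore, in_bout=gt.in_bout,
                     w_couple=0.0, tau=config.tau)
    return pf.experienced, gt


def simulate_transmission_chain(config: SimConfig, n_generations: int = 5,
                                n_releases: int = 12,
                                chain_id: str = "chain1",
                                explore_boost: float = 5.0,
                                explore_decay: float = 2.5,
                                ) -> list[ChainFlight]:
    """Simulate one transmission chain of ``n_generations × n_releases``.

    Generation 1 is solo flights of the founding bird; each later
    generation pairs the previous generation's naive bird (now the
    experienced bird, its exploration drive decayed) with a fresh naive
    bird whose bout-start probability is elevated early in the generation:
    ``p_explore · (1 + boost · exp(−(release−1)/decay))``.
    """
    config.validate()
    if n_generations < 1:
        raise ConfigurationError("n_generations must be >= 1")
    if n_releases < 2:
        raise ConfigurationError("n_releases must be >= 2")
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(n_generations * n_releases) >> 1  # keep < 2^31
    config = replace(config, stop_at_home=True)   # real tracks end at the loft
    flights: list[ChainFlight] = []
    for g in range(1, n_generations + 1):
        for r in range(1, n_releases + 1):
            seed = int(seeds[(g - 1) * n_releases + (r - 1)])
            if g == 1:
                cfg = replace(config, seed=seed)
                traj, gt = simulate_solo_flight(
                    cfg, bird_id=f"{chain_id}-b1",
                    metadata=(chain_id, g, r))
                flights.append(ChainFlight(chain_id, g, r, None, traj, gt))
            else:
                boost = 1.0 + explore_boost * math.exp(-(r - 1) / explore_decay)
                cfg = replace(config, seed=seed,
                              p_explore=min(config.p_explore * boost, 1.0))
                pf, gt = simulate_pair_flight(
                    cfg,
                    bird_ids=(f"{chain_id}-b{g - 1}", f"{chain_id}-b{g}"),
                    metadata=(chain_id, g, r))
                flights.append(ChainFlight(chain_id, g, r, pf, None, gt))
    return flights


def generate_binary_channel(n: int, p_flip: float, seed: int = 0):
    """Analytic test channel: target copies the source one step late,
    flipped with probability ``p_flip``.

    True TE(source→target) at k=1 is ``1 − H_b(p_flip)`` bits; the reverse
    direction carries none.  Returns two :class:`RotationSeries`.
    """
    from .encoding import RotationSeries

    if not 0.0 <= p_flip <= 0.5:
        raise ConfigurationError("p_flip must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    source = rng.integers(0, 2, size=n).astype(np.int8)
    flips = (rng.random(n) < p_flip)
    target = np.empty(n, dtype=np.int8)
    target[0] = rng.integers(0, 2)
    target[1:] = source[:-1] ^ flips[1:]
    return (RotationSeries(symbols=source, sampling_period=0.2, bird_id="src"),
            RotationSeries(symbols=target, sampling_period=0.2, bird_id="tgt"))
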