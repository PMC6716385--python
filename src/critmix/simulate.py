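"""Two-session categorization study generator.

Emulates the statistical structure the mixture analysis assumes: latent
criterion groups with group-specific item scales, normally distributed
thresholds around group means (unit variance), S-shaped Bernoulli responding,
a minority of participants switching criterion group between sessions, mild
threshold drift for everyone else, and occasional *unknown* answers missing
completely at random.

Default configuration
---------------------
Dimensions mirror a two-session study of 60 completers plus 250 archival
single-session respondents answering 24 items (370 entries x 24 items once
sessions are stacked).  The remaining defaults are calibrated so the realized
two-session inconsistency rate falls in the upper half of the 10-25% band
typical of repeated category-membership tasks: steepness alpha = 6 (fairly
deterministic responding near the scale extremes), between-group item-scale
correlation 0.5 (the two criteria agree on clear members and non-members and
disagree on borderline items), threshold drift correlation rho = 0.98 for
non-switchers, and a 2% unknown rate.  One participant in five switches
criterion group in session 2.

Threshold drift is a stationary AR(1) step,

    theta_2 = mu_g + rho (theta_1 - mu_g) + sqrt(1 - rho^2) eps,

which preserves the Normal(mu_g, 1) marginal the model assumes; rho = 0 is a
fresh redraw and ``redraw_thresholds=False`` keeps theta_1 exactly.  Group
switchers draw a fresh threshold from the new group's hyper-distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import ResponseTable
from .model import ModelParameters, response_probability


@dataclass
class SimulationConfig:
    """Parameters of the synthetic two-session study (see module docstring)."""

    n_participants: int = 60
    n_archival: int = 250
    n_items: int = 24
    G: int = 2
    pi: tuple = (0.5, 0.5)
    mu: tuple = (-0.5, 0.5)
    alpha: tuple = (6.0, 6.0)
    beta: np.ndarray | None = None        # explicit (G, I) matrix, else recipe
    between_group_corr: float = 0.5       # item-scale correlation across groups
    switch_fraction: float = 0.2          # share of participants switching group
    redraw_thresholds: bool = True        # degree drift for non-switchers
    theta_drift_corr: float = 0.98        # AR(1) rho of the drift step
    unknown_rate: float = 0.02            # MCAR unknown contamination per cell
    seed: int = 0
    category_id: str = "synthetic"

    def validate(self) -> list[str]:
        """Return every violation (empty list when valid)."""
        errors = []
        if self.n_participants < 0 or self.n_archival < 0 or self.n_items < 1:
            errors.append("n_participants/n_archival must be >= 0 and n_items >= 1")
        if self.G < 1:
            errors.append("G must be >= 1")
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (self.G,) or not np.isclose(pi.sum(), 1.0) or (pi < 0).any():
            errors.append("pi must be a length-G probability simplex")
        if np.asarray(self.mu, dtype=float).shape != (self.G,):
            errors.append("mu must have length G")
        alpha = np.asarray(self.alpha, dtype=float)
        if alpha.shape != (self.G,) or (alpha <= 0).any():
            errors.append("alpha must be length G and strictly positive")
        if self.beta is not None and np.asarray(self.beta).shape != (self.G, self.n_items):
            errors.append("explicit beta must be G x n_items")
        if not 0.0 <= self.switch_fraction <= 1.0:
            errors.append("switch_fraction must be in [0, 1]")
        if not 0.0 <= self.unknown_rate <= 1.0:
            errors.append("unknown_rate must be in [0, 1]")
        if not -1.0 <= self.between_group_corr <= 1.0:
            errors.append("between_group_corr must be in [-1, 1]")
        if not 0.0 <= self.theta_drift_corr <= 1.0:
            errors.append("theta_drift_corr must be in [0, 1]")
        if self.switch_fraction > 0 and self.G < 2:
            errors.append("switch_fraction > 0 requires G >= 2")
        return errors

    def check(self) -> None:
        errors = self.validate()
        if errors:
            raise ValueError("invalid simulation config: " + "; ".join(errors))

    def participant_ids(self) -> list[str]:
        width = max(2, len(str(self.n_participants)))
        return [f"p{k + 1:0{width}d}" for k in range(self.n_participants)]

    def archival_ids(self) -> list[str]:
        width = max(3, len(str(self.n_archival)))
        return [f"a{k + 1:0{width}d}" for k in range(self.n_archival)]

    def item_ids(self) -> list[str]:
        width = max(2, len(str(self.n_items)))
        return [f"item{k + 1:0{width}d}" for k in range(self.n_items)]


@dataclass
class SimulationTruth:
    """Ground truth of one simulated two-session study."""

    params_session1: ModelParameters
    params_session2: ModelParameters
    switcher_ids: set
    table: ResponseTable
    participant_ids: list = field(default_factory=list)

    def entry_groups(self, entry_index: pd.DataFrame) -> np.ndarray:
        """True (0-based) group of each new-data entry in a merged matrix."""
        pos = {pid: k for k, pid in enumerate(self.participant_ids)}
        out = np.full(len(entry_index), -1)
        for row, (pid, sess, prov) in enumerate(
            entry_index[["participant", "session", "provenance"]].itertuples(index=False)
        ):
            if prov == "archival" or pid not in pos:
                continue
            params = self.params_session1 if sess == 1 else self.params_session2
            out[row] = params.z[pos[pid]]
        return out


def _draw_beta(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.beta is not None:
        return np.asarray(cfg.beta, dtype=float).copy()
    base = rng.normal(size=cfg.n_items)
    rows = [base]
    c = cfg.between_group_corr
    for _ in range(1, cfg.G):
        rows.append(c * base + np.sqrt(max(0.0, 1 - c**2)) * rng.normal(size=cfg.n_items))
    return np.stack(rows)


def sample_population(cfg: SimulationConfig,
                      rng: np.random.Generator | None = None) -> ModelParameters:
    """Draw a complete population state from the generative model."""
    cfg.check()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pi = np.asarray(cfg.pi, dtype=float)
    mu = np.asarray(cfg.mu, dtype=float)
    beta = _draw_beta(cfg, rng)
    z = rng.choice(cfg.G, size=cfg.n_participants, p=pi)
    theta = rng.normal(mu[z], 1.0)
    return ModelParameters(pi=pi, z=z, beta=beta, theta=theta, mu=mu,
                           alpha=np.asarray(cfg.alpha, dtype=float))


def generate_session(params: ModelParameters, session: int, cfg: SimulationConfig,
                     rng: np.random.Generator | None = None,
                     participant_ids: list[str] | None = None,
                     provenance: str = "synthetic") -> ResponseTable:
    """Bernoulli responses for one session, with MCAR unknown contamination."""
    cfg.check()
    if rng is None:
        rng = np.random.default_rng(cfg.seed + session)
    if participant_ids is None:
        participant_ids = cfg.participant_ids()[: params.n_entries]
    items = cfg.item_ids()[: params.n_items]
    p = response_probability(params.beta[params.z],
                             params.theta[:, None],
                             params.alpha[params.z][:, None])
    yes = rng.random(p.shape) < p
    unknown = rng.random(p.shape) < cfg.unknown_rate
    resp = np.where(unknown, "unknown", np.where(yes, "yes", "no"))
    records = {
        "participant": np.repeat(participant_ids, len(items)),
        "category": cfg.category_id,
        "item": np.tile(items, len(participant_ids)),
        "session": session,
        "response": resp.reshape(-1),
        "provenance": provenance,
    }
    return ResponseTable(pd.DataFrame(records))


def generate_two_session_study(cfg: SimulationConfig) -> SimulationTruth:
    """Simulate both sessions with criterial switching and degree drift."""
    cfg.check()
    if cfg.switch_fraction > 0 and cfg.G < 2:
        raise ValueError("switching requires at least two groups")
    rng = np.random.default_rng(cfg.seed)
    params1 = sample_population(cfg, rng)
    pids = cfg.participant_ids()

    n_switch = int(round(cfg.switch_fraction * cfg.n_participants))
    switch_idx = rng.permutation(cfg.n_participants)[:n_switch]
    is_switch = np.zeros(cfg.n_participants, dtype=bool)
    is_switch[switch_idx] = True

    z2 = params1.z.copy()
    if n_switch:
        # move each switcher to a different group, uniformly among the others
        offsets = rng.integers(1, cfg.G, size=n_switch)
        z2[switch_idx] = (params1.z[switch_idx] + offsets) % cfg.G

    mu = params1.mu
    rho = cfg.theta_drift_corr if cfg.redraw_thresholds else 1.0
    drift = (mu[z2] + rho * (params1.theta - mu[params1.z])
             + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal(size=cfg.n_participants))
    fresh = rng.normal(mu[z2], 1.0)
    theta2 = np.where(is_switch, fresh, drift)

    params2 = ModelParameters(pi=params1.pi, z=z2, beta=params1.beta,
                              theta=theta2, mu=mu, alpha=params1.alpha)
    t1 = generate_session(params1, 1, cfg, rng, pids)
    t2 = generate_session(params2, 2, cfg, rng, pids)
    table = ResponseTable.concat([t1, t2])
    return SimulationTruth(
        params_session1=params1, params_session2=params2,
        switcher_ids={pids[k] for k in switch_idx}, table=table,
        participant_ids=pids,
    )


def generate_archival(cfg: SimulationConfig,
                      return_truth: bool = False):
    """Single-session respondents from an independent draw of the same population.

    Shares beta, mu, alpha and pi with the two-session study simulated from
    the same config (they describe the same category) but has its own
    respondents.  With ``return_truth`` the sampled parameters are returned
    alongside the table.
    """
    cfg.check()
    rng = np.random.default_rng([cfg.seed, 104729])
    beta = _draw_beta(cfg, np.random.default_rng(cfg.seed))  # same category scales
    arch_cfg = replace(cfg, n_participants=cfg.n_archival, beta=beta)
    params = sample_population(arch_cfg, rng)
    if cfg.n_archival == 0:
        table = ResponseTable(pd.DataFrame(
            columns=["participant", "category", "item", "session", "response",
                     "provenance"]).astype({"session": int}))
        return (table, params) if return_truth else table
    table = generate_session(params, 1, arch_cfg, rng,
                             cfg.archival_ids(), provenance="archival")
    if return_truth:
        return table, params
    return table


@dataclass
class StudyData:
    """A complete simulated dataset: two-session study plus archival block."""

    truth: SimulationTruth
    archival: ResponseTable
    archival_params: ModelParameters

    def entry_groups(self, entry_index: pd.DataFrame) -> np.ndarray:
        """True (0-based) group of every entry, archival included."""
        out = self.truth.entry_groups(entry_index)
        arch_ids = sorted(self.archival.df["participant"].unique())
        pos = {pid: k for k, pid in enumerate(arch_ids)}
        for row, (pid, prov) in enumerate(
            entry_index[["participant", "provenance"]].itertuples(index=False)
        ):
            if prov == "archival":
                out[row] = self.archival_params.z[pos[pid]]
        return out


def generate_study(cfg: SimulationConfig) -> StudyData:
    """Two-session study plus archival respondents, with all ground truth."""
    truth = generate_two_session_study(cfg)
    archival, params = generate_archival(cfg, return_truth=True)
    return StudyData(truth=truth, archival=archival, archival_params=params)
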