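"""Population dynamics of the 5-fluorouracil survival screen.

Each lineage is a (PAM, edited-status) genotype.  One screening round is:

1. **Induction** — unedited cells of PAM p acquire an inactivating edit with
   probability ``π_p + μ``, where π_p is the base-editing probability for
   that PAM and μ a small background-escape rate (spontaneous ``upp``
   inactivation, which the assay cannot distinguish from editing).
2. **Selection/growth** — under 5-Fu, edited (upp-) lineages keep relative
   fitness 1 while unedited (upp+) lineages are scaled by ``s < 1``, a single
   multiplicative factor absorbing killing and growth differences over the
   round.
3. **Bottleneck** — proportions are renormalized; in stochastic mode a
   multinomial draw of ``bottleneck_size`` colonies replaces the population,
   emulating harvesting ~1e5 clones from the plate between rounds.

Deterministic mode propagates expected proportions exactly; stochastic mode
draws binomial edits and the multinomial bottleneck.  For a two-strain
start (functional π_f vs invalid π_i = 0, all unedited, μ = 0) one round
multiplies the functional:invalid odds by (π_f + (1 − π_f)·s) / s — the
closed form used to validate the step-by-step update.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .amplicon import AmpliconTemplate

__all__ = ["ScreenParams", "ScreenPopulation", "init_population",
           "simulate_round", "run_screen", "couple_to_reads",
           "two_strain_odds_update"]


@dataclass(frozen=True)
class ScreenParams:
    """Parameters of one screening campaign.

    ``edit_prob`` maps PAM → per-induction editing probability π_p (default
    0.1 for the canonical-PAM anchor: roughly one cell in ten survives 5-Fu
    after induction with an NGG PAM).  ``unedited_survival`` is the relative
    per-round fitness s of unedited cells under 5-Fu (default 0.02: strong
    but imperfect counterselection).  ``background_escape`` μ (default 1e-6)
    is the per-round spontaneous upp-inactivation probability.
    """

    edit_prob: dict[str, float] = field(default_factory=dict)
    background_escape: float = 1e-6
    unedited_survival: float = 0.02
    bottleneck_size: int = 100_000
    rounds: int = 2
    mode: str = "deterministic"
    seed: int = 0
    default_edit_prob: float = 0.0

    def __post_init__(self) -> None:
        probs = list(self.edit_prob.values()) + [
            self.background_escape, self.unedited_survival, self.default_edit_prob
        ]
        for v in probs:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"probabilities must be in [0, 1], got {v}")
        if self.bottleneck_size < 1:
            raise ValueError("bottleneck_size must be positive")
        if self.rounds < 0:
            raise ValueError("rounds must be non-negative")
        if self.mode not in ("deterministic", "stochastic"):
            raise ValueError("mode must be 'deterministic' or 'stochastic'")

    def pi(self, pam: str) -> float:
        return self.edit_prob.get(pam, self.default_edit_prob)


@dataclass
class ScreenPopulation:
    """Abundances of (PAM, edited-status) genotypes at one round.

    Abundances are expected masses in deterministic mode and colony counts
    in stochastic mode; proportions are derived on demand.
    """

    pams: list[str]
    unedited: np.ndarray
    edited: np.ndarray
    round_index: int = 0

    def __post_init__(self) -> None:
        self.unedited = np.asarray(self.unedited, dtype=float)
        self.edited = np.asarray(self.edited, dtype=float)
        if self.unedited.shape != (len(self.pams),) or self.edited.shape != (
            len(self.pams),
        ):
            raise ValueError("abundance arrays must match the PAM list")
        if (self.unedited < 0).any() or (self.edited < 0).any():
            raise ValueError("abundances must be non-negative")
        if self.total <= 0:
            raise ValueError("total abundance must be positive")

    @property
    def total(self) -> float:
        return float(self.unedited.sum() + self.edited.sum())

    def proportions(self) -> np.ndarray:
        """Per-PAM proportion of the whole population (edited + unedited)."""
        return (self.unedited + self.edited) / self.total

    def edited_fractions(self) -> np.ndarray:
        """Per-PAM edited fraction (NaN for extinct lineages)."""
        tot = self.unedited + self.edited
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.edited / tot, np.nan)

    def proportion_of(self, pam: str) -> float:
        i = self.pams.index(pam)
        return float((self.unedited[i] + self.edited[i]) / self.total)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "round": self.round_index,
                "pam": self.pams,
                "proportion": self.proportions(),
                "edited_fraction": self.edited_fractions(),
            }
        )


def init_population(
    weights: dict[str, float],
    edited_fraction: dict[str, float] | float = 0.0,
    total: float = 1.0,
) -> ScreenPopulation:
    """Population with per-PAM abundance ∝ weights, split edited/unedited."""
    if not weights:
        raise ValueError("weights must be non-empty")
    pams = sorted(weights)
    w = np.array([float(weights[p]) for p in pams])
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be non-negative and not all zero")
    w = w / w.sum() * float(total)
    if isinstance(edited_fraction, (int, float)):
        ef = np.full(len(pams), float(edited_fraction))
    else:
        ef = np.array([float(edited_fraction.get(p, 0.0)) for p in pams])
    if (ef < 0).any() or (ef > 1).any():
        raise ValueError("edited fractions must be probabilities")
    return ScreenPopulation(pams, unedited=w * (1 - ef), edited=w * ef)


def two_strain_odds_update(pi_f: float, s: float) -> float:
    """Closed-form one-round multiplier of the functional:invalid odds.

    For two all-unedited lineages with editing probabilities π_f and 0,
    μ = 0 and unedited survival s, one induction+selection round multiplies
    the odds by (π_f + (1 − π_f)·s) / s.
    """
    if s <= 0:
        raise ValueError("closed form requires s > 0")
    return (pi_f + (1.0 - pi_f) * s) / s


def simulate_round(
    pop: ScreenPopulation,
    params: ScreenParams,
    rng: np.random.Generator | None = None,
) -> ScreenPopulation:
    """One induction → selection → renormalization/bottleneck round."""
    pi = np.array([params.pi(p) + params.background_escape for p in pop.pams])
    np.clip(pi, 0.0, 1.0, out=pi)
    s = params.unedited_survival

    if params.mode == "deterministic":
        converted = pop.unedited * pi
        unedited = (pop.unedited - converted) * s
        edited = pop.edited + converted
        total = unedited.sum() + edited.sum()
        if total <= 0:
            raise RuntimeError("population went extinct (s=0 and nothing edited)")
        return ScreenPopulation(
            pop.pams, unedited / total, edited / total, pop.round_index + 1
        )

    if rng is None:
        rng = np.random.default_rng(params.seed)
    u = np.round(pop.unedited).astype(np.int64)
    e = np.round(pop.edited).astype(np.int64)
    converted = rng.binomial(u, pi)
    u = u - converted
    e = e + converted
    # survival thinning of unedited cells, then multinomial bottleneck
    u = rng.binomial(u, s)
    masses = np.concatenate([u, e]).astype(float)
    tot = masses.sum()
    if tot <= 0:
        raise RuntimeError("population went extinct during selection")
    draw = rng.multinomial(params.bottleneck_size, masses / tot)
    k = len(pop.pams)
    return ScreenPopulation(
        pop.pams, draw[:k].astype(float), draw[k:].astype(float),
        pop.round_index + 1,
    )


def run_screen(
    init: ScreenPopulation, params: ScreenParams
) -> list[ScreenPopulation]:
    """Apply ``params.rounds`` screening rounds; returns [initial, r1, r2, ...]."""
    rng = (
        np.random.default_rng(params.seed)
        if params.mode == "stochastic"
        else None
    )
    pop = init
    if params.mode == "stochastic":
        # work in colony counts from the start
        scale = params.bottleneck_size / pop.total
        pop = ScreenPopulation(
            pop.pams,
            np.round(pop.unedited * scale),
            np.round(pop.edited * scale),
            pop.round_index,
        )
    traj = [pop]
    for _ in range(params.rounds):
        pop = simulate_round(pop, params, rng)
        traj.append(pop)
    return traj


def trajectory_frame(traj: list[ScreenPopulation]) -> pd.DataFrame:
    """Long-format (round, pam, proportion, edited_fraction) table."""
    return pd.concat([p.to_frame() for p in traj], ignore_index=True)


def couple_to_reads(
    pop: ScreenPopulation,
    template: AmpliconTemplate,
    n_reads: int,
    error_model=None,
    seed: int = 0,
    **kwargs,
):
    """Sequence a population: amplicon reads with the population's PAM
    weights and edited fractions (plus the generator's ground truth)."""
    from .reads import generate_library_reads

    tot = pop.unedited + pop.edited
    weights = {p: float(t) for p, t in zip(pop.pams, tot) if t > 0}
    ef = {
        p: float(e / t)
        for p, e, t in zip(pop.pams, pop.edited, tot)
        if t > 0
    }
    return generate_library_reads(
        weights, ef, template, n_reads, error_model, seed, **kwargs
    )
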