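"""Synthetic woman-level microdata with a known district TFR-CPR law.

Access to the individual-level survey data the analysis was designed for is
restricted, so every downstream stage is validated by parameter recovery on
simulated populations instead.  The generator plants a district-level
log-linear structure

    log TFR_i = beta0 + beta1 * CPR_i + eps_i,   eps_i ~ N(0, sigma_eps),

with CPR_i uniform on a configurable range, and then emits woman-level
records consistent with it: women aged 15-49 at interview (uniform across
the seven 5-year groups), a currently-married flag, a Bernoulli(CPR/100)
any-method use flag among married women, and birth histories drawn from a
Poisson process whose age-group rates follow a fixed schedule shape rescaled
so the district's all-women TFR equals its planted tfr_true.

Only married women bear simulated births (use of contraception outside
union contributes nothing to fertility here), so married women's rates carry
a 1/married_fraction factor to keep the all-women TFR unbiased.  The causal
contraception-fertility link exists only at the district level — exactly the
level the downstream regression can see; there is no individual-level
use-to-birth mechanism.

Reproducibility: a single seed keys the run; each district draws from a
substream seeded by (seed, district_id), so enlarging the simulation leaves
existing districts' records bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .fertility import N_AGE_GROUPS

#: Normalized 7-element age pattern of fertility (15-19 ... 45-49), a
#: typical schedule peaking at 20-29; sums to 1.  Only the scaled total
#: matters downstream.
ASFR_SHAPE = np.array([0.055, 0.27, 0.31, 0.19, 0.10, 0.055, 0.02])

#: CMC of January 2016 — mid survey period of a 2015-16 round.
DEFAULT_INTERVIEW_CMC = (2016 - 1900) * 12 + 1


@dataclass
class SimConfig:
    """Study-design parameters of a simulated survey.

    Defaults mirror the observed national landscape the analysis targets:
    640 districts (32 states x 20), CPR spanning 2.7-84.8%, and the pooled
    log-linear law log TFR = 1.199 - 0.0083*CPR with district residual
    sd 0.1.
    """

    n_states: int = 32
    districts_per_state: int = 20
    women_per_district: int = 1000
    beta0: float = 1.199
    beta1: float = -0.0083
    sigma_eps: float = 0.1
    cpr_range: tuple[float, float] = (2.7, 84.8)
    interview_cmc: int = DEFAULT_INTERVIEW_CMC
    married_fraction: float = 0.72
    seed: int = 0
    asfr_shape: np.ndarray = field(default_factory=lambda: ASFR_SHAPE.copy())

    def __post_init__(self):
        if min(self.n_states, self.districts_per_state, self.women_per_district) < 1:
            raise ConfigError("counts must all be >= 1")
        if self.sigma_eps < 0:
            raise ConfigError("sigma_eps must be >= 0")
        lo, hi = self.cpr_range
        if not (0 <= lo < hi <= 100):
            raise ConfigError("cpr_range must satisfy 0 <= low < high <= 100")
        if self.beta1 > 0:
            raise ConfigError("beta1 must be <= 0 (contraception lowers fertility)")
        if not (0 < self.married_fraction <= 1):
            raise ConfigError("married_fraction must be in (0, 1]")
        self.asfr_shape = np.asarray(self.asfr_shape, float)
        if self.asfr_shape.shape != (N_AGE_GROUPS,) or np.any(self.asfr_shape < 0):
            raise ConfigError("asfr_shape must be 7 nonnegative values")
        total = self.asfr_shape.sum()
        if total <= 0:
            raise ConfigError("asfr_shape must have positive total")
        self.asfr_shape = self.asfr_shape / total

    @property
    def n_districts(self) -> int:
        return self.n_states * self.districts_per_state


def _district_rng(seed: int, district_id: int) -> np.random.Generator:
    """Stable per-district substream: adding districts never perturbs others."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(district_id)]))


def generate_district_truths(config: SimConfig) -> pd.DataFrame:
    """Draw the latent (CPR, TFR) pair for every district.

    CPR is uniform on ``cpr_range``; the district residual eps is
    N(0, sigma_eps); tfr_true = exp(beta0 + beta1*cpr + eps).  Deterministic
    given the seed.  Columns: district_id, state_id, cpr_true, tfr_true,
    eps_true.
    """
    rows = []
    lo, hi = config.cpr_range
    for d in range(1, config.n_districts + 1):
        rng = _district_rng(config.seed, d)
        cpr = rng.uniform(lo, hi)
        eps = rng.normal(0.0, config.sigma_eps) if config.sigma_eps > 0 else 0.0
        rows.append(
            {
                "district_id": d,
                "state_id": (d - 1) // config.districts_per_state + 1,
                "cpr_true": cpr,
                "tfr_true": float(np.exp(config.beta0 + config.beta1 * cpr + eps)),
                "eps_true": eps,
            }
        )
    return pd.DataFrame(rows)


def generate_microdata(
    truths: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit woman and birth records realizing the district truths.

    Per district: ages at interview uniform over the 7 five-year groups
    (month resolution); marriage ~ Bernoulli(married_fraction); any-method
    use ~ Bernoulli(cpr_true/100) among married women; births over the
    36-month window from per-month Poisson rates
    ``shape_a * tfr_true / 5 / 12 / married_fraction`` applied to married
    women in group a.  All dates are CMC; weights default to 1.0.
    """
    if truths.empty:
        raise ConfigError("truths must be nonempty")
    women_frames, birth_frames = [], []
    n = config.women_per_district
    iv = int(config.interview_cmc)

    for row in truths.itertuples(index=False):
        d = int(row.district_id)
        rng = _district_rng(config.seed, d)
        rng = np.random.default_rng(rng.spawn(1)[0])  # keep truths/microdata draws apart

        group = rng.integers(0, N_AGE_GROUPS, size=n)
        within = rng.integers(0, 60, size=n)
        age_months = 180 + 60 * group + within
        dob = iv - age_months
        married = rng.random(n) < config.married_fraction
        using = married & (rng.random(n) < row.cpr_true / 100.0)
        woman_id = d * 100_000 + np.arange(1, n + 1)

        women_frames.append(
            pd.DataFrame(
                {
                    "woman_id": woman_id,
                    "state_id": int(row.state_id),
                    "district_id": d,
                    "dob_cmc": dob,
                    "interview_cmc": iv,
                    "currently_married": married,
                    "using_any_method": using,
                    "weight": 1.0,
                }
            )
        )

        # Monthly hazard for married women in group a; zero for unmarried.
        lam = config.asfr_shape * row.tfr_true / 5.0 / 12.0 / config.married_fraction
        win_lo, win_hi = iv - 36, iv - 1
        for a in range(N_AGE_GROUPS):
            g_lo = dob + 12 * (15 + 5 * a)
            g_hi = dob + 12 * (20 + 5 * a) - 1
            lo = np.maximum(win_lo, g_lo)
            hi = np.minimum(win_hi, g_hi)
            months = np.clip(hi - lo + 1, 0, None)
            mean = lam[a] * months * married
            counts = rng.poisson(mean)
            k = int(counts.sum())
            if k == 0:
                continue
            idx = np.repeat(np.arange(n), counts)
            offsets = rng.integers(0, months[idx])
            birth_frames.append(
                pd.DataFrame(
                    {
                        "woman_id": woman_id[idx],
                        "birth_cmc": lo[idx] + offsets,
                    }
                )
            )

    women = pd.concat(women_frames, ignore_index=True)
    if birth_frames:
        births = (
            pd.concat(birth_frames, ignore_index=True)
            .sort_values(["woman_id", "birth_cmc"], ignore_index=True)
        )
    else:
        births = pd.DataFrame({"woman_id": pd.Series(dtype=np.int64),
                               "birth_cmc": pd.Series(dtype=np.int64)})
    return women, births


def simulate(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: truths plus the microdata realizing them."""
    truths = generate_district_truths(config)
    women, births = generate_microdata(truths, config)
    return truths, women, births
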