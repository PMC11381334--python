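"""Pooled-screen simulator: dose-response, noise, censoring, recovery.

Generates synthetic per-animal per-barcode peak-area tables with the
structure of a real pooled LNP screen, so the quantitation and ranking
pipeline can be exercised and its operating characteristics measured
without animal data.

The generative model, per animal a and LNP i dosed at d_i in a pool:

    area(a, i) = E_i(d_i) * A_a * M_{a,i}

where E_i is a Hill/Emax dose-response (each LNP's potency profile),
A_a is an animal-level lognormal factor shared by every barcode in that
animal (inter-animal variability: uptake, expression, sampling), and
M_{a,i} is a per-measurement lognormal factor (MS measurement noise).
Both lognormals have unit mean, parameterised by their coefficient of
variation.  Areas below the LOQ are censored at the LOQ.  Because the
animal factor is shared across barcodes, per-animal normalization to a
reference barcode cancels it exactly -- the key property that makes
pooled screening robust to inter-animal variability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quant import normalize_to_reference, rank_lnps

__all__ = [
    "LnpModel",
    "ScreenDesign",
    "RecoveryResult",
    "dose_response",
    "simulate_screen",
    "ranking_recovery",
    "pooled_vs_individual_concordance",
    "group_size_for_effect",
    "example_models",
]


@dataclass(frozen=True)
class LnpModel:
    """Hill/Emax potency profile of one LNP.

    ``emax`` is the saturating protein signal (arbitrary units), ``ed50``
    the dose (mg/kg) at half-maximal signal, ``hill`` the slope.
    """

    label: str
    emax: float
    ed50: float
    hill: float = 1.0

    def __post_init__(self) -> None:
        if self.emax <= 0:
            raise ValueError("emax must be > 0")
        if self.ed50 <= 0:
            raise ValueError("ed50 must be > 0")
        if self.hill < 0:
            raise ValueError("hill must be >= 0")


def dose_response(model: LnpModel, dose: float) -> float:
    """Expected signal at ``dose``: emax * d^h / (ed50^h + d^h); 0 at d=0."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if dose == 0:
        return 0.0
    dh = dose**model.hill
    return model.emax * dh / (model.ed50**model.hill + dh)


@dataclass(frozen=True)
class ScreenDesign:
    """Pools, group size, dose cap, noise levels and censoring for one screen.

    Each pool is a list of ``(LnpModel, dose)`` entries dosed together to
    one group of ``n_animals``.  ``animal_cv`` and ``ms_cv`` are lognormal
    coefficients of variation for the animal-level and measurement-level
    noise.  ``interaction`` (default 0: pooling leaves each LNP's behaviour
    unchanged) attenuates each LNP's signal by exp(-interaction * other
    pool dose), a stress-test knob for the ranking.
    """

    pools: tuple[tuple[tuple[LnpModel, float], ...], ...]
    n_animals: int = 5
    total_dose_cap: float = 0.5
    animal_cv: float = 0.3
    ms_cv: float = 0.2
    loq: float = 0.0
    interaction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        for k, pool in enumerate(self.pools):
            total = sum(dose for _, dose in pool)
            if total > self.total_dose_cap + 1e-12:
                raise ValueError(
                    f"pool {k} total dose {total:.3f} exceeds cap "
                    f"{self.total_dose_cap} mg/kg"
                )

    def barcode_of(self, label: str) -> str:
        return f"BC_{label}"

    def assignment(self) -> dict[str, str]:
        out = {}
        for pool in self.pools:
            for model, _ in pool:
                out[self.barcode_of(model.label)] = model.label
        return out


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean lognormal factors with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv * cv)
    sigma = math.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=size)


def simulate_screen(
    design: ScreenDesign, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one screen; returns (peak table, ground truth).

    The peak table has the quantitation pipeline's input columns
    (animal_id, group_id, barcode_id, peak_area, below_loq, peak_area_raw).
    The truth table carries each LNP's expected signal and true rank within
    its pool (rank 1 = highest expected signal).
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    peak_rows = []
    truth_rows = []
    for p, pool in enumerate(design.pools):
        group_id = f"pool{p + 1}"
        expected = []
        for model, dose in pool:
            e = dose_response(model, dose)
            if design.interaction:
                other = sum(d for m, d in pool if m.label != model.label)
                e *= math.exp(-design.interaction * other)
            expected.append(e)
        order = stats.rankdata([-e for e in expected], method="average")
        for (model, dose), e, rk in zip(pool, expected, order):
            truth_rows.append(
                {
                    "group_id": group_id,
                    "lnp": model.label,
                    "barcode_id": design.barcode_of(model.label),
                    "dose": dose,
                    "expected_signal": e,
                    "true_rank": rk,
                }
            )
        animal_factor = _lognormal_factors(rng, design.animal_cv, design.n_animals)
        ms_factor = _lognormal_factors(
            rng, design.ms_cv, (design.n_animals, len(pool))
        )
        for a in range(design.n_animals):
            animal_id = f"{group_id}_a{a + 1}"
            for i, (model, dose) in enumerate(pool):
                area = expected[i] * animal_factor[a] * ms_factor[a, i]
                below = area < design.loq
                peak_rows.append(
                    {
                        "animal_id": animal_id,
                        "group_id": group_id,
                        "barcode_id": design.barcode_of(model.label),
                        "peak_area": design.loq if below else area,
                        "peak_area_raw": area,
                        "below_loq": below,
                    }
                )
    return pd.DataFrame(peak_rows), pd.DataFrame(truth_rows)


def _estimated_order(peaks: pd.DataFrame, design: ScreenDesign) -> list[str]:
    """Rank LNPs by group-mean fold change to the first LNP of each pool.

    With one pool this is the pipeline's standard reference normalization;
    with several pools each pool is normalized to its own first-listed LNP
    (the shared standard), then ranked jointly.
    """
    frames = []
    for p, pool in enumerate(design.pools):
        ref_bc = design.barcode_of(pool[0][0].label)
        sub = peaks[peaks["group_id"] == f"pool{p + 1}"]
        frames.append(normalize_to_reference(sub, ref_bc))
    normalized = pd.concat(frames, ignore_index=True)
    ranking = rank_lnps(normalized, design.assignment())
    return ranking.order


@dataclass(frozen=True)
class RecoveryResult:
    """Monte-Carlo estimate of ranking recovery."""

    probability: float
    standard_error: float
    n_replicates: int
    pair_recovery: pd.DataFrame = field(repr=False)


def ranking_recovery(
    design: ScreenDesign, n_replicates: int, seed: int | None = None
) -> RecoveryResult:
    """Probability that the estimated ranking equals the true one.

    Each replicate simulates the whole screen and ranks LNPs by group-mean
    fold change; recovery is exact equality with the expected-signal order.
    ``pair_recovery[i, j]`` is the fraction of replicates ordering LNP i
    above LNP j (diagonal is NaN).  The standard error is binomial.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    labels = [m.label for pool in design.pools for m, _ in pool]
    truth = simulate_screen(design, np.random.default_rng(0))[1]
    true_order = truth.sort_values(
        ["expected_signal", "lnp"], ascending=[False, True]
    )["lnp"].tolist()
    idx = {lab: i for i, lab in enumerate(labels)}
    above = np.zeros((len(labels), len(labels)))
    hits = 0
    for _ in range(n_replicates):
        peaks, _ = simulate_screen(design, rng)
        est = _estimated_order(peaks, design)
        if est == true_order:
            hits += 1
        for i, lab_i in enumerate(est):
            for lab_j in est[i + 1 :]:
                above[idx[lab_i], idx[lab_j]] += 1
    prob = hits / n_replicates
    se = math.sqrt(prob * (1 - prob) / n_replicates)
    pair = above / n_replicates
    np.fill_diagonal(pair, np.nan)
    pair_df = pd.DataFrame(pair, index=labels, columns=labels)
    return RecoveryResult(
        probability=prob,
        standard_error=se,
        n_replicates=n_replicates,
        pair_recovery=pair_df,
    )


def pooled_vs_individual_concordance(
    models: Sequence[LnpModel],
    dose: float,
    n_replicates: int,
    n_animals: int = 5,
    animal_cv: float = 0.3,
    ms_cv: float = 0.2,
    total_dose_cap: float = 0.5,
    seed: int = 0,
) -> float:
    """Fraction of replicates where pooled and individual arms rank alike.

    One arm doses all LNPs together in a single pool (ranking by fold
    change to the first LNP); the other doses each LNP to its own group
    (ranking by group-mean raw signal, as with a per-group protein assay).
    Equal per-LNP dose in both arms.  With no LNP-LNP interaction the two
    arms measure the same quantities, so discordance reflects only noise.
    """
    pooled = ScreenDesign(
        pools=(tuple((m, dose) for m in models),),
        n_animals=n_animals,
        total_dose_cap=total_dose_cap,
        animal_cv=animal_cv,
        ms_cv=ms_cv,
    )
    individual = ScreenDesign(
        pools=tuple(((m, dose),) for m in models),
        n_animals=n_animals,
        total_dose_cap=total_dose_cap,
        animal_cv=animal_cv,
        ms_cv=ms_cv,
    )
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_replicates):
        pooled_peaks, _ = simulate_screen(pooled, rng)
        pooled_order = _estimated_order(pooled_peaks, pooled)
        ind_peaks, _ = simulate_screen(individual, rng)
        means = ind_peaks.groupby("barcode_id")["peak_area"].mean()
        assignment = individual.assignment()
        ind_order = [
            assignment[bc] for bc in means.sort_values(ascending=False).index
        ]
        if pooled_order == ind_order:
            agree += 1
    return agree / n_replicates


def group_size_for_effect(
    effect_sd_units: float, alpha: float = 0.05, power: float = 0.8
) -> int:
    """Two-sample normal-approximation group size for a d-SD mean shift.

    n per group = ceil(2 * (z_{1-alpha/2} + z_power)^2 / d^2).  A change of
    two SD units at alpha 0.05 and 80% power needs n = 4; in-vivo screens
    round up to 5 for attrition margin.
    """
    if effect_sd_units <= 0:
        raise ValueError("effect_sd_units must be > 0")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    return math.ceil(2 * (z_a + z_b) ** 2 / effect_sd_units**2)


def example_models() -> list[LnpModel]:
    """Five illustrative LNP potency profiles, one per classic ionisable lipid.

    Ordered by potency as such lipids typically rank in hepatic mRNA
    delivery (MC3 > KC2 > C12-200 > DLin-DMA > DOTAP).  The parameter
    values are illustrative placeholders for simulation demos, not fitted
    to any measured dose-response.
    """
    return [
        LnpModel("MC3", emax=100.0, ed50=0.10, hill=1.2),
        LnpModel("KC2", emax=50.0, ed50=0.12, hill=1.2),
        LnpModel("C12-200", emax=25.0, ed50=0.15, hill=1.1),
        LnpModel("DLin-DMA", emax=12.0, ed50=0.18, hill=1.0),
        LnpModel("DOTAP", emax=6.0, ed50=0.25, hill=1.0),
    ]
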