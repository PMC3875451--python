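"""Rheostat (signal x threshold) simulator for carp scale-pattern phenotypes.

Scale formation is modeled as a graded signal over the body surface: a
baseline profile with preferential bands below the dorsal fin, over the
lateral line and above the belly, attenuated multiplicatively by the fish's
genotype.  A scale forms wherever the attenuated, noise-perturbed signal
clears a fixed threshold, so progressively lower signal levels shrink the
pattern from full cover through linear and mirror down to nude.  The same
genotype attenuation is dose-coupled to pharyngeal-teeth retention and
per-fin defect severity, which lets whole crosses be simulated end-to-end
(gamete sampling, pre-hatching loss of the lethal class, per-fish scale map,
fins and teeth) from a single seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .genetic_model import (
    AlleleModel,
    Genotype,
    NonviableParentError,
    Phenotype,
    STANDARD_MODEL,
    is_viable,
    offspring_genotype_distribution,
    phenotype_of,
    viable_genotypes,
)
from .inference import ObservedCross
from .phenotype_scoring import (
    DEFAULT_WEIGHTS,
    Fin,
    FinState,
    FishRecord,
    SEVERITY_ORDER,
)

__all__ = [
    "SignalProfile",
    "RheostatParams",
    "CrossResult",
    "default_profile",
    "default_attenuation",
    "simulate_scale_map",
    "expected_scale_coverage",
    "classify_scale_map",
    "simulate_cross",
    "simulate_cross_counts",
]


@dataclass(frozen=True)
class SignalProfile:
    """Baseline signal over a dorso-ventral x head-to-tail grid.

    Rows index positions along the dorso-ventral body axis, columns
    head-to-tail.  The profile carries local maxima in the dorsal-line,
    lateral-line and ventral (belly) bands — the locations where scales
    persist longest as the signal falls.
    """

    baseline: np.ndarray
    dorsal_rows: tuple[int, ...]
    lateral_rows: tuple[int, ...]
    ventral_rows: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.baseline.ndim != 2:
            raise ValueError("baseline must be a 2-D grid")
        if np.any(self.baseline < 0):
            raise ValueError("baseline signal must be non-negative")
        flank = self.baseline[self.flank_mask()]
        for name, rows in (
            ("dorsal", self.dorsal_rows),
            ("ventral", self.ventral_rows),
        ):
            if self.baseline[list(rows)].mean() <= flank.mean():
                raise ValueError(f"{name} band must be a local signal maximum")

    @property
    def shape(self) -> tuple[int, int]:
        return self.baseline.shape

    def band_rows(self) -> tuple[int, ...]:
        return tuple(self.dorsal_rows) + tuple(self.lateral_rows) + tuple(
            self.ventral_rows
        )

    def flank_mask(self) -> np.ndarray:
        mask = np.ones(self.baseline.shape[0], dtype=bool)
        mask[list(self.band_rows())] = False
        return np.broadcast_to(mask[:, None], self.baseline.shape)


def default_profile(n_rows: int = 100, n_cols: int = 30) -> SignalProfile:
    """Default signal profile: flank level 1.0 with dorsal (3.0), lateral
    (1.5) and ventral (2.6) bands, each a few rows thick."""
    base = np.full((n_rows, n_cols), 1.0)

    def rows(center_frac: float, thickness: int) -> tuple[int, ...]:
        center = int(round(center_frac * (n_rows - 1)))
        lo = max(center - thickness // 2, 0)
        return tuple(range(lo, min(lo + thickness, n_rows)))

    dorsal = rows(0.13, max(n_rows // 12, 1))
    lateral = rows(0.45, max(n_rows // 25, 1))
    ventral = rows(0.88, max(n_rows // 12, 1))
    base[list(dorsal)] = 3.0
    base[list(lateral)] = 1.5
    base[list(ventral)] = 2.6
    return SignalProfile(base, dorsal, lateral, ventral)


#: Default genotype-class attenuation multipliers (configurable).
CLASS_ATTENUATION = {
    Phenotype.SCALED: 1.0,
    Phenotype.LINEAR: 0.55,
    Phenotype.SCATTERED: 0.35,
    Phenotype.NUDE: 0.12,
}


def default_attenuation(model: AlleleModel = STANDARD_MODEL) -> dict[str, float]:
    """Attenuation multiplier per viable genotype, derived from the phenotype
    class defaults (wild-type 1.0, decreasing towards nude)."""
    return {
        str(g): CLASS_ATTENUATION[phenotype_of(g, model)]
        for g in viable_genotypes(model)
    }


@dataclass(frozen=True)
class RheostatParams:
    """Tunable constants of the rheostat realization.

    ``attenuation`` maps genotype strings to signal multipliers in [0, 1];
    genotypes absent from the mapping fall back to their phenotype-class
    default.  ``threshold`` is the signal level ("green line") a position
    must clear for a scale to form.  ``noise_sd`` perturbs the signal per
    position, ``fish_sd`` is the lognormal sd of a per-fish overall signal
    level (modifier-gene variation).  Teeth retention probability is
    ``expit(teeth_intercept + teeth_dose_slope * attenuation)`` (calibrated
    so simulated means approximate the observed gradient: scaled ~9.3 of 10,
    nude < 1); per-fin defect severity is drawn with success probability
    ``expit(fin_intercept - fin_dose_slope * attenuation)``.
    """

    attenuation: Mapping[str, float] = field(default_factory=default_attenuation)
    threshold: float = 0.7
    noise_sd: float = 0.08
    fish_sd: float = 0.08
    teeth_dose_slope: float = 5.715
    teeth_intercept: float = -3.128
    fin_dose_slope: float = 9.395
    fin_intercept: float = 1.702
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.noise_sd < 0 or self.fish_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        for g, a in self.attenuation.items():
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"attenuation for {g} must lie in [0, 1]")
        # class ordering: scale cover never increases from scaled to nude
        order = [Phenotype.SCALED, Phenotype.IRREGULAR, Phenotype.MIRROR, Phenotype.NUDE]
        levels = [self._class_level(ph) for ph in order]
        if any(a < b for a, b in itertools.pairwise(levels)):
            raise ValueError(
                "attenuation must be non-increasing from scaled through "
                "irregular and mirror to nude"
            )
        object.__setattr__(self, "attenuation", dict(self.attenuation))

    def _class_level(self, ph: Phenotype) -> float:
        cls = Phenotype.SCATTERED if ph in (Phenotype.IRREGULAR, Phenotype.MIRROR) else ph
        reference = {
            Phenotype.SCALED: "SSnn",
            Phenotype.LINEAR: "SSNn",
            Phenotype.SCATTERED: "ssnn",
            Phenotype.NUDE: "ssNn",
        }[cls]
        return self.attenuation.get(reference, CLASS_ATTENUATION[cls])

    def attenuation_of(
        self, genotype: Genotype, model: AlleleModel = STANDARD_MODEL
    ) -> float:
        key = str(genotype)
        if key in self.attenuation:
            return self.attenuation[key]
        ph = phenotype_of(genotype, model)
        cls = (
            Phenotype.SCATTERED
            if ph in (Phenotype.IRREGULAR, Phenotype.MIRROR)
            else ph
        )
        return CLASS_ATTENUATION[cls]

    def teeth_retention(self, attenuation: float) -> float:
        return float(expit(self.teeth_intercept + self.teeth_dose_slope * attenuation))

    def fin_severity(self, attenuation: float) -> float:
        return float(expit(self.fin_intercept - self.fin_dose_slope * attenuation))


def simulate_scale_map(
    genotype: Genotype,
    profile: SignalProfile | None = None,
    params: RheostatParams | None = None,
    rng: np.random.Generator | None = None,
    model: AlleleModel = STANDARD_MODEL,
    fish_level: float = 1.0,
) -> np.ndarray:
    """Realize one boolean scale map: a scale forms at a position iff
    ``attenuation * fish_level * (baseline + noise) >= threshold``."""
    if not is_viable(genotype, model):
        raise NonviableParentError(
            f"genotype {genotype} is not viable under the {model.name!r} model"
        )
    profile = profile or default_profile()
    params = params or RheostatParams()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    atten = params.attenuation_of(genotype, model)
    noise = (
        rng.normal(0.0, params.noise_sd, size=profile.shape)
        if params.noise_sd > 0
        else 0.0
    )
    signal = atten * fish_level * (profile.baseline + noise)
    return signal >= params.threshold


def expected_scale_coverage(
    attenuation: float,
    profile: SignalProfile | None = None,
    params: RheostatParams | None = None,
) -> float:
    """Closed-form expected fraction of positions bearing a scale at a given
    attenuation (monotone non-decreasing in the attenuation)."""
    profile = profile or default_profile()
    params = params or RheostatParams()
    if attenuation <= 0:
        return 0.0
    cut = params.threshold / attenuation
    if params.noise_sd == 0:
        return float((profile.baseline >= cut).mean())
    return float(norm.sf((cut - profile.baseline) / params.noise_sd).mean())


def classify_scale_map(
    scale_map: np.ndarray,
    profile: SignalProfile | None = None,
    coverage_scaled: float = 0.95,
    coverage_nude: float = 0.05,
    coverage_mirror: float = 0.25,
    line_complete: float = 0.8,
    line_populated: float = 0.5,
    flank_sparse: float = 0.10,
) -> tuple[Phenotype, str | None]:
    """Rule-based phenotype call from a boolean scale map.

    Near-total coverage is scaled and a (near-)empty map is nude (sub-typed
    ``nude1`` when residual scales remain; further nude sub-typing uses fin
    severity and is applied at cross-simulation time).  A complete dorsal
    line with a populated lateral line over sparse flanks is linear; dorsal
    plus ventral lines only, at low coverage, is mirror; everything else —
    substantial cover without tight row structure — is irregular.
    """
    profile = profile or default_profile()
    if scale_map.shape != profile.shape:
        raise ValueError("scale map shape must match the signal profile")
    cov = float(scale_map.mean())
    if cov >= coverage_scaled:
        return Phenotype.SCALED, None
    if cov <= coverage_nude:
        return Phenotype.NUDE, ("nude1" if scale_map.any() else None)
    dorsal = float(scale_map[list(profile.dorsal_rows)].mean())
    lateral = float(scale_map[list(profile.lateral_rows)].mean())
    ventral = float(scale_map[list(profile.ventral_rows)].mean())
    flank = float(scale_map[profile.flank_mask()].mean())
    if dorsal >= line_complete and lateral >= line_populated and flank < flank_sparse:
        return Phenotype.LINEAR, None
    if (
        cov <= coverage_mirror
        and dorsal >= line_complete
        and ventral >= line_populated
        and lateral < line_populated
        and flank < flank_sparse / 2
    ):
        return Phenotype.MIRROR, None
    return Phenotype.IRREGULAR, None


@dataclass(frozen=True)
class CrossResult:
    """Outcome of one simulated cross."""

    fish: tuple[FishRecord, ...]
    observed: ObservedCross
    lethal_count: int
    genotype_counts: dict


def _nude_subtype(fin_score: float, residual_scales: int) -> str:
    if residual_scales > 0:
        return "nude1"
    if fin_score >= 6.0:
        return "nude3"
    if fin_score >= 3.5:
        return "nude2"
    return "nude1"


def _draw_fins(rng: np.random.Generator, q: float) -> dict[Fin, FinState]:
    # severity level per fin ~ Binomial(4, q): expected per-fin weight equals q
    levels = rng.binomial(len(SEVERITY_ORDER) - 1, q, size=len(Fin))
    return {fin: SEVERITY_ORDER[level] for fin, level in zip(Fin, levels)}


def simulate_cross(
    p1: Genotype,
    p2: Genotype,
    n: int,
    model: AlleleModel = STANDARD_MODEL,
    params: RheostatParams | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    realize: str = "split",
    profile: SignalProfile | None = None,
    label: str | None = None,
) -> CrossResult:
    """Simulate a full cross: ``n`` zygotes drawn by gamete sampling, lethal
    zygotes counted and removed (pre-hatching loss), and every survivor
    realized as a :class:`FishRecord` with category, per-fin states and a
    teeth count, all from one seeded RNG stream.

    ``realize`` selects how the scattered class splits into irregular/mirror:
    ``"split"`` applies the model's ``scattered_split`` at the observation
    layer; ``"rheostat"`` simulates and classifies a scale map per fish.  The
    two mechanisms are mutually exclusive within a run.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if realize not in ("split", "rheostat"):
        raise ValueError("realize must be 'split' or 'rheostat'")
    params = params or RheostatParams()
    if rng is None:
        if seed is None:
            seed = params.seed
        if seed is None:
            raise ValueError("a seed (or an explicit rng) is required")
        rng = np.random.default_rng(seed)
    profile = profile or (default_profile() if realize == "rheostat" else None)
    label = label or f"{p1}x{p2}"

    gdist = offspring_genotype_distribution(p1, p2, model)
    genotypes = list(gdist)
    draws = rng.multinomial(n, [float(q) for q in gdist.values()])
    lethal_count = 0
    fish: list[FishRecord] = []
    counts: dict[Phenotype, int] = {}
    idx = 0
    for genotype, k in zip(genotypes, draws):
        if k == 0:
            continue
        ph = phenotype_of(genotype, model)
        if ph is Phenotype.LETHAL:
            lethal_count += int(k)
            continue
        atten = params.attenuation_of(genotype, model)
        p_teeth = params.teeth_retention(atten)
        q_fin = params.fin_severity(atten)
        for _ in range(int(k)):
            residual = 0
            subtype_hint: str | None = None
            if realize == "rheostat":
                level = rng.lognormal(0.0, params.fish_sd) if params.fish_sd else 1.0
                smap = simulate_scale_map(
                    genotype, profile, params, rng, model, fish_level=level
                )
                category, subtype_hint = classify_scale_map(smap, profile)
                residual = int(smap.sum())
            else:
                category = ph
                if category is Phenotype.SCATTERED:
                    category = (
                        Phenotype.IRREGULAR
                        if rng.random() < model.scattered_split
                        else Phenotype.MIRROR
                    )
            fins = _draw_fins(rng, q_fin)
            teeth = int(rng.binomial(10, p_teeth))
            subtype = None
            if category is Phenotype.NUDE:
                score = sum(DEFAULT_WEIGHTS.weight(s) for s in fins.values())
                subtype = subtype_hint or _nude_subtype(score, residual)
            record = FishRecord(
                id=f"{label}-{idx:05d}",
                family=label,
                category=category,
                fins=fins,
                teeth_count=teeth,
                nude_subtype=subtype,
            )
            fish.append(record)
            counts[category] = counts.get(category, 0) + 1
            idx += 1
    observed = ObservedCross(
        label=label,
        parent_phenotypes=(phenotype_of(p1, model), phenotype_of(p2, model)),
        total_n=len(fish),
        counts=counts,
        location="simulated",
        metadata={"lethal_count": lethal_count, "n_zygotes": n, "realize": realize},
    )
    genotype_counts = {
        str(g): int(k) for g, k in zip(genotypes, draws) if k > 0
    }
    return CrossResult(tuple(fish), observed, lethal_count, genotype_counts)


def simulate_cross_counts(
    p1: Genotype,
    p2: Genotype,
    n: int,
    model: AlleleModel = STANDARD_MODEL,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    label: str | None = None,
) -> tuple[ObservedCross, int]:
    """Fast counts-only cross simulation (no per-fish records): zygote
    categories are drawn directly from the cross distribution and scattered
    survivors split by the model's ``scattered_split``.  Returns the observed
    cross and the lethal zygote count."""
    if n <= 0:
        raise ValueError("n must be positive")
    if rng is None:
        if seed is None:
            raise ValueError("a seed (or an explicit rng) is required")
        rng = np.random.default_rng(seed)
    label = label or f"{p1}x{p2}"
    from .genetic_model import cross_distribution

    dist = cross_distribution(p1, p2, model)
    cats = list(dist.probabilities)
    draws = rng.multinomial(n, [float(p) for p in dist.probabilities.values()])
    counts: dict[Phenotype, int] = {}
    lethal = 0
    for cat, k in zip(cats, draws):
        if k == 0:
            continue
        if cat is Phenotype.LETHAL:
            lethal = int(k)
        elif cat is Phenotype.SCATTERED:
            irr = int(rng.binomial(int(k), model.scattered_split))
            if irr:
                counts[Phenotype.IRREGULAR] = irr
            if int(k) - irr:
                counts[Phenotype.MIRROR] = int(k) - irr
        else:
            counts[cat] = int(k)
    observed = ObservedCross(
        label=label,
        parent_phenotypes=(phenotype_of(p1, model), phenotype_of(p2, model)),
        total_n=int(sum(counts.values())),
        counts=counts,
        location="simulated",
        metadata={"lethal_count": lethal, "n_zygotes": n},
    )
    return observed, lethal
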