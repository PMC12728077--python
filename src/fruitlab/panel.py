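"""Synthetic germplasm-panel generator.

Emulates a 137-accession eggplant panel measured with a colorimeter at two
stages (harvest maturity "H" and physiological ripeness "P"), scored for
ten ordinal DUS characteristics, and genotyped at 24 co-dominant SSR
markers, together with the ground truth needed for recovery tests.

The generating model ties everything to one latent anthocyanin factor:

* five causal SSR markers each contribute a fixed fraction of the latent
  variance through the dosage of a common "dark" allele (frequencies
  shared across subpopulations, so the causal signal is not confounded
  with structure); the remainder is environmental noise;
* the latent factor, through its rank, assigns each accession to a
  harvest colour tier (white < green < light < medium < dark purple, in
  order of anthocyanin load) and to an anthocyanin score on the 1–9 DUS
  note scale;
* skin colour is drawn from tier-specific truncated-normal boxes whose
  bounds respect the classification thresholds (white L* ≥ 72,
  green a* ≤ −6, violet b* ≤ −3.5, red b* ≥ −1.5), with purple lightness
  decreasing continuously with the anthocyanin score;
* DUS notes are monotone transforms of the score with ±1 ordinal jitter;
* ripening follows the transition rule white/green → yellow,
  light/medium purple → ochre, dark purple → brown.

Non-causal markers carry 4–8 alleles with Balding–Nichols divergence
between the two subpopulations, giving detectable population structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

__all__ = [
    "PanelConfig",
    "ColorCategorySpec",
    "SyntheticTruth",
    "PanelData",
    "generate_panel",
    "generate_structure_runs",
    "HARVEST_SPECS",
    "RIPENESS_SPECS",
    "DEFAULT_CATEGORY_MIX",
]

# Mixture over harvest categories x intensity.  Purple-dominant, as is
# typical of eggplant germplasm panels.
DEFAULT_CATEGORY_MIX: dict[str, float] = {
    "white": 0.12,
    "green": 0.18,
    "violet_light": 0.09,
    "red_light": 0.08,
    "violet_medium": 0.12,
    "red_medium": 0.08,
    "violet_dark": 0.17,
    "red_dark": 0.16,
}

#: anthocyanin-score (DUS note scale) interval per harvest tier
_TIER_SCORE_RANGE = {
    "white": (0.8, 1.6),
    "green": (1.2, 2.8),
    "light": (1.5, 4.2),
    "medium": (4.8, 6.2),
    "dark": (6.8, 9.2),
}

_TIERS = ("white", "green", "light", "medium", "dark")


@dataclass(frozen=True)
class ColorCategorySpec:
    """Truncated-normal sampling spec for one colour category and stage."""

    label: str
    stage: str  # "H" or "P"
    mean: tuple[float, float, float]
    sd: tuple[float, float, float]
    box: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]

    def __post_init__(self) -> None:
        for m, s, (lo, hi) in zip(self.mean, self.sd, self.box):
            if s <= 0:
                raise ValueError(f"{self.label}: sd must be positive")
            if not lo <= m <= hi:
                raise ValueError(f"{self.label}: mean {m} outside box [{lo}, {hi}]")


# Harvest-stage boxes.  The L* entry for green/purple is a placeholder
# mean; the realised mean decreases with the anthocyanin score (see
# _harvest_mean) while staying inside the box.
HARVEST_SPECS: dict[str, ColorCategorySpec] = {
    "white": ColorCategorySpec("white", "H", (80, 0, 6), (3, 1.2, 2), ((72, 90), (-3, 3), (2, 12))),
    "green": ColorCategorySpec("green", "H", (56, -12, 20), (2.5, 2.5, 3), ((40, 68), (-20, -6), (10, 30))),
    "violet": ColorCategorySpec("violet", "H", (43, 4, -6.5), (2.0, 2.0, 1.5), ((20, 66), (0, 10), (-11, -3.5))),
    "red": ColorCategorySpec("red", "H", (43, 8, 1.5), (2.0, 2.5, 1.5), ((20, 66), (2, 15), (-1.5, 6))),
}

RIPENESS_SPECS: dict[str, ColorCategorySpec] = {
    "yellow": ColorCategorySpec("yellow", "P", (75, 4, 35), (3.5, 2.0, 3.5), ((66, 85), (0, 10), (26, 45))),
    "ochre": ColorCategorySpec("ochre", "P", (55, 12, 22), (3.5, 3.0, 3.0), ((46, 63), (5, 19), (15, 29))),
    "brown": ColorCategorySpec("brown", "P", (32, 9, 9), (3.5, 3.0, 2.5), ((23, 40), (3, 16), (3, 15))),
}


@dataclass(frozen=True)
class PanelConfig:
    """Generator configuration; defaults are the reference study design."""

    n_accessions: int = 137
    n_fruits_per_accession: int = 5
    n_markers: int = 24
    n_subpopulations: int = 2
    causal_marker_indices: tuple[int, ...] = (2, 6, 11, 16, 21)
    causal_effect_r2: float = 0.20
    category_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MIX)
    )
    subpop_divergence: float = 0.25  # Balding-Nichols F_ST for neutral markers
    fruit_sd: float = 1.2  # within-accession (fruit-to-fruit) sd per axis
    missing_rate: float = 0.0
    striped_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_accessions", "n_fruits_per_accession", "n_markers", "n_subpopulations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(i < 0 or i >= self.n_markers for i in self.causal_marker_indices):
            raise ValueError("causal_marker_indices must lie in [0, n_markers)")
        if len(set(self.causal_marker_indices)) != len(self.causal_marker_indices):
            raise ValueError("causal_marker_indices must be unique")
        total_r2 = self.causal_effect_r2 * len(self.causal_marker_indices)
        if self.causal_effect_r2 < 0 or total_r2 > 1.0 + 1e-9:
            raise ValueError(
                f"causal effects explain {total_r2:.3f} of the latent variance; "
                "the total must not exceed 1"
            )
        mix_sum = float(sum(self.category_mix.values()))
        if abs(mix_sum - 1.0) > 1e-9:
            raise ValueError(f"category_mix must sum to 1, got {mix_sum}")
        if set(self.category_mix) != set(DEFAULT_CATEGORY_MIX):
            raise ValueError(f"category_mix keys must be {sorted(DEFAULT_CATEGORY_MIX)}")
        if not 0 <= self.missing_rate < 1 or not 0 <= self.striped_fraction <= 1:
            raise ValueError("missing_rate/striped_fraction out of range")

    def marker_names(self) -> list[str]:
        return [f"ssr{i + 1:02d}" for i in range(self.n_markers)]

    def accession_ids(self) -> list[str]:
        w = max(3, len(str(self.n_accessions)))
        return [f"acc{i + 1:0{w}d}" for i in range(self.n_accessions)]


@dataclass
class SyntheticTruth:
    """Ground truth: per-accession labels/means and per-marker effects."""

    accessions: pd.DataFrame
    markers: pd.DataFrame


@dataclass
class PanelData:
    """Everything one synthetic panel run produces."""

    measurements: pd.DataFrame
    dus: pd.DataFrame
    genotypes: pd.DataFrame
    truth: SyntheticTruth
    config: PanelConfig


def _tn(rng: np.random.Generator, mean, sd, lo, hi, size=None) -> np.ndarray:
    """Truncated-normal draw inside [lo, hi]."""
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _largest_remainder(props: np.ndarray, n: int) -> np.ndarray:
    """Integer counts summing to n, proportional to props."""
    raw = props * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def _standardise(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def _draw_genotypes(cfg: PanelConfig, rng: np.random.Generator, subpop: np.ndarray):
    """Allele-index pairs (n, m, 2), allele sizes, and causal dosages."""
    n, m = cfg.n_accessions, cfg.n_markers
    causal = set(cfg.causal_marker_indices)
    geno_idx = np.zeros((n, m, 2), dtype=int)
    allele_sizes: list[np.ndarray] = []
    causal_allele_size = np.full(m, np.nan)
    fst = cfg.subpop_divergence
    for j in range(m):
        if j in causal:
            # strong functional variant: two common alleles, no divergence
            p0 = rng.uniform(0.35, 0.5)
            base = np.array([p0, 1 - p0])
            freqs = np.tile(base, (cfg.n_subpopulations, 1))
        else:
            k = int(rng.integers(4, 9))
            base = rng.dirichlet(np.ones(k))
            conc = base * (1 - fst) / fst
            freqs = np.vstack(
                [rng.dirichlet(np.clip(conc, 1e-6, None)) for _ in range(cfg.n_subpopulations)]
            )
        sizes = 150 + 6 * j + 2 * np.arange(freqs.shape[1])
        allele_sizes.append(sizes)
        if j in causal:
            causal_allele_size[j] = sizes[0]
        for s in range(cfg.n_subpopulations):
            rows = np.flatnonzero(subpop == s)
            geno_idx[rows, j, :] = rng.choice(freqs.shape[1], size=(rows.size, 2), p=freqs[s])
    dosage = {j: (geno_idx[:, j, :] == 0).sum(axis=1) for j in causal}
    return geno_idx, allele_sizes, causal_allele_size, dosage


def _harvest_mean(tier: str, subtype: str | None, score: float, rng: np.random.Generator):
    """True accession-level harvest colour, inside the category box."""
    if tier == "white":
        spec = HARVEST_SPECS["white"]
        mean_l = spec.mean[0]
    elif tier == "green":
        spec = HARVEST_SPECS["green"]
        mean_l = 62.0 - 3.0 * score
    else:
        spec = HARVEST_SPECS[subtype]  # type: ignore[index]
        mean_l = 66.0 - 4.8 * score
    L = float(_tn(rng, mean_l, spec.sd[0], *spec.box[0]))
    a = float(_tn(rng, spec.mean[1], spec.sd[1], *spec.box[1]))
    b = float(_tn(rng, spec.mean[2], spec.sd[2], *spec.box[2]))
    return (L, a, b), spec


def generate_panel(config: PanelConfig | None = None, seed: int | None = None) -> PanelData:
    """Generate one synthetic panel; fully reproducible from the seed.

    Parameters
    ----------
    config : PanelConfig, optional
        Study design; defaults to the reference 137-accession design.
    seed : int, optional
        Overrides ``config.seed`` when given.
    """
    cfg = config or PanelConfig()
    if seed is not None:
        cfg = replace(cfg, seed=int(seed))
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_accessions
    ids = cfg.accession_ids()
    markers = cfg.marker_names()

    # subpopulations: balanced assignment, shuffled
    subpop = rng.permutation(np.arange(n) % cfg.n_subpopulations)

    geno_idx, allele_sizes, causal_size, dosage = _draw_genotypes(cfg, rng, subpop)

    # latent anthocyanin factor (unit variance by construction)
    r2 = cfg.causal_effect_r2
    latent = np.zeros(n)
    for j in cfg.causal_marker_indices:
        latent += math.sqrt(r2) * _standardise(dosage[j].astype(float))
    resid = 1.0 - r2 * len(cfg.causal_marker_indices)
    if resid > 1e-12:
        latent += math.sqrt(resid) * _standardise(rng.standard_normal(n))

    # tier assignment by latent rank (anthocyanin ordering)
    mix = cfg.category_mix
    tier_props = np.array(
        [
            mix["white"],
            mix["green"],
            mix["violet_light"] + mix["red_light"],
            mix["violet_medium"] + mix["red_medium"],
            mix["violet_dark"] + mix["red_dark"],
        ]
    )
    tier_counts = _largest_remainder(tier_props, n)
    order = np.argsort(latent + rng.uniform(-1e-9, 1e-9, n), kind="stable")
    tier = np.empty(n, dtype=object)
    score = np.empty(n)
    start = 0
    for t, cnt in zip(_TIERS, tier_counts):
        block = order[start : start + cnt]
        lo, hi = _TIER_SCORE_RANGE[t]
        for r, idx in enumerate(block):
            tier[idx] = t
            score[idx] = lo + (hi - lo) * ((r + 0.5) / cnt) if cnt else lo
        start += cnt

    # violet/red subtype inside each purple tier (exact mix counts)
    subtype = np.full(n, None, dtype=object)
    for t in ("light", "medium", "dark"):
        rows = np.flatnonzero(tier == t)
        if rows.size == 0:
            continue
        denom = mix[f"violet_{t}"] + mix[f"red_{t}"]
        pv = mix[f"violet_{t}"] / denom if denom > 0 else 0.5
        n_violet = int(round(pv * rows.size))
        lab = np.array(["violet"] * n_violet + ["red"] * (rows.size - n_violet), dtype=object)
        subtype[rows] = rng.permutation(lab)

    # pulp colour: green pulp certain for green skin, graded for purple
    pulp_p = {"white": 0.0, "green": 1.0, "light": 0.4, "medium": 0.25, "dark": 0.15}
    pulp_green = rng.random(n) < np.array([pulp_p[t] for t in tier])

    striped = np.zeros(n, dtype=bool)
    if cfg.striped_fraction > 0:
        purple_rows = np.flatnonzero(np.isin(tier, ("light", "medium", "dark")))
        k = int(round(cfg.striped_fraction * purple_rows.size))
        striped[rng.choice(purple_rows, size=k, replace=False)] = True

    ripeness_map = {"white": "yellow", "green": "yellow", "light": "ochre", "medium": "ochre", "dark": "brown"}

    h_mean = np.zeros((n, 3))
    p_mean = np.zeros((n, 3))
    rip = np.empty(n, dtype=object)
    h_box = []
    for i in range(n):
        (hm, spec) = _harvest_mean(tier[i], subtype[i], score[i], rng)
        if striped[i]:
            gm, _ = _harvest_mean("green", None, 2.0, rng)
            hm = tuple(0.5 * (np.array(hm) + np.array(gm)))
        h_mean[i] = hm
        h_box.append(spec.box)
        rip[i] = ripeness_map[tier[i]]
        rspec = RIPENESS_SPECS[rip[i]]
        p_mean[i] = [float(_tn(rng, m, s, lo, hi)) for m, s, (lo, hi) in zip(rspec.mean, rspec.sd, rspec.box)]

    # fruit-level measurements, clipped to the category box
    rows = []
    for i in range(n):
        for stage, mean, box in (
            ("H", h_mean[i], h_box[i]),
            ("P", p_mean[i], RIPENESS_SPECS[rip[i]].box),
        ):
            vals = mean + rng.normal(0.0, cfg.fruit_sd, size=(cfg.n_fruits_per_accession, 3))
            for ax, (lo, hi) in enumerate(box):
                vals[:, ax] = np.clip(vals[:, ax], lo, hi)
            for f in range(cfg.n_fruits_per_accession):
                rows.append((ids[i], stage, f + 1, *np.round(vals[f], 2)))
    measurements = pd.DataFrame(rows, columns=["accession", "stage", "fruit", "L", "a", "b"])

    # DUS notes: monotone in the anthocyanin score with +-1 ordinal jitter
    def note(x: np.ndarray) -> np.ndarray:
        return np.clip(np.round(x), 1, 9).astype(int)

    jit = lambda: rng.integers(-1, 2, size=n)  # noqa: E731
    fsch_code = {"white": 1, "green": 2, "light": 3, "medium": 3, "dark": 3}
    fscp_code = {"yellow": 3, "ochre": 5, "brown": 7}
    dus = pd.DataFrame(
        {
            "accession": ids,
            "ACH": note(score + jit()),
            "ACS": note(score + jit()),
            "ILG": note(rng.normal(5, 1.5, n)),
            "ACL": note(score + jit()),
            "FC": note(2 + 0.5 * score + jit()),
            "FPC": np.where(pulp_green, 2, 1),
            "FSCH": np.array([fsch_code[t] for t in tier]),
            "IFC": np.where(tier == "white", np.nan, note(score + jit()).astype(float)),
            "FG": rng.integers(3, 8, n),
            "FSCP": note(np.array([fscp_code[r] for r in rip]) + jit()),
        }
    )

    # genotype table: two size columns per marker
    geno_cols: dict[str, np.ndarray] = {"accession": np.array(ids, dtype=object)}
    for j, mk in enumerate(markers):
        pair = np.sort(allele_sizes[j][geno_idx[:, j, :]], axis=1).astype(float)
        if cfg.missing_rate > 0:
            miss = rng.random(n) < cfg.missing_rate
            pair[miss] = np.nan
        geno_cols[f"{mk}_1"] = pair[:, 0]
        geno_cols[f"{mk}_2"] = pair[:, 1]
    genotypes = pd.DataFrame(geno_cols)

    acc_truth = pd.DataFrame(
        {
            "accession": ids,
            "subpopulation": subpop,
            "harvest_tier": tier,
            "harvest_category": np.where(np.isin(tier, ("light", "medium", "dark")), "purple", tier),
            "harvest_subtype": subtype,
            "intensity": np.where(np.isin(tier, ("light", "medium", "dark")), tier, None),
            "striped": striped,
            "pulp_green": pulp_green,
            "ripeness_category": rip,
            "anthocyanin_score": np.round(score, 4),
            "latent": np.round(latent, 6),
            "H_L": h_mean[:, 0],
            "H_a": h_mean[:, 1],
            "H_b": h_mean[:, 2],
            "P_L": p_mean[:, 0],
            "P_a": p_mean[:, 1],
            "P_b": p_mean[:, 2],
        }
    )
    marker_truth = pd.DataFrame(
        {
            "marker": markers,
            "causal": [j in set(cfg.causal_marker_indices) for j in range(cfg.n_markers)],
            "causal_allele_size": causal_size,
            "effect_r2": [
                cfg.causal_effect_r2 if j in set(cfg.causal_marker_indices) else 0.0
                for j in range(cfg.n_markers)
            ],
        }
    )
    return PanelData(measurements, dus, genotypes, SyntheticTruth(acc_truth, marker_truth), cfg)


def generate_structure_runs(
    true_k: int,
    k_min: int = 1,
    k_max: int = 15,
    runs_per_k: int = 5,
    seed: int = 0,
    noise_sd: float = 5.0,
) -> pd.DataFrame:
    """Simulate Bayesian-clustering run summaries (K, run, LnPD).

    Mean LnP(D) rises steeply up to ``true_k`` and then flattens, with
    i.i.d. run-to-run noise, so the ΔK statistic peaks at ``true_k``.
    """
    if runs_per_k < 2:
        raise ValueError("need at least 2 runs per K for the ΔK run-to-run sd")
    if k_max - k_min + 1 < 3:
        raise ValueError("K range must span at least 3 values for interior ΔK")
    if not k_min < true_k < k_max:
        raise ValueError("true_k must be interior to [k_min, k_max]")
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(k_min, k_max + 1):
        mean = -8000.0 + 300.0 * min(k, true_k) + 8.0 * max(0, k - true_k)
        for run in range(1, runs_per_k + 1):
            rows.append((k, run, round(mean + rng.normal(0.0, noise_sd), 2)))
    return pd.DataFrame(rows, columns=["K", "run", "LnPD"])
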