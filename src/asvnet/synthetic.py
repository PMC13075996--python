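"""Synthetic ASV count data with planted microbe-phenotype structure.

The generator emulates a rumen/faecal 16S amplicon experiment: a few
hundred ASVs over ~56 animals, a heavy-tailed compositional base drawn
from a Dirichlet, log-normal sequencing depths, multinomial count
sampling, and three inter-correlated continuous phenotypes (feed
efficiency EFF, methane yield CH4Y and the acetate:propionate ratio
ACET_PROP).  Ground truth is planted at two levels:

* *direct* ASVs share a latent per-sample driver with one phenotype, so
  their CSS-log2 abundances correlate with it at a configurable target
  strength (default |r| ~ 0.3, the moderate range typical of
  ASV-phenotype associations);
* *mediated* ASVs are noisy copies of a direct ASV's latent signal with
  no independent phenotype term — they correlate with the phenotype
  only through their mediator, which is exactly the indirect structure
  the PCIT trio scan is meant to strip.

Effects are injected on the latent log-abundance scale *before* count
sampling so that they survive normalisation; the effect size is
deflated by a fixed attenuation constant that accounts for the
correlation loss through multinomial sampling and the CSS-log2
transform.  Family labels follow a Zipf-like distribution, with one
designated family over-represented among the direct ASVs so that
enrichment recovery can be tested against known truth.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io_tables import CountMatrix, PhenotypeTable, TaxonomyTable, parse_lineage
import pandas as pd

# Correlation attenuation through multinomial count sampling + CSS-log2,
# measured once on the default configuration at large n and frozen.
ATTENUATION = 0.86

_FAMILY_POOL = [
    "Bacteroidaceae", "Lachnospiraceae", "Ruminococcaceae", "Prevotellaceae",
    "Fibrobacteraceae", "Succinivibrionaceae", "Oscillospiraceae",
    "Acutalibacteraceae", "Paludibacteraceae", "Rikenellaceae",
    "Christensenellaceae", "Spirochaetaceae", "Selenomonadaceae",
    "Anaerovoracaceae", "Acidaminococcaceae", "Erysipelotrichaceae",
    "Eubacteriaceae", "Clostridiaceae", "Peptostreptococcaceae",
    "Veillonellaceae", "Streptococcaceae", "Lactobacillaceae",
    "Bifidobacteriaceae", "Methanobacteriaceae", "Saccharofermentanaceae",
]

_BACTEROIDOTA = {"Bacteroidaceae", "Prevotellaceae", "Paludibacteraceae",
                 "Rikenellaceae"}

PHENOTYPES = ("EFF", "CH4Y", "ACET_PROP")

#: phenotype rescaling targets (mean, SD) — dairy-herd-like values
DEFAULT_PHENOTYPE_TARGETS = {
    "EFF": (1.46, 0.15),
    "CH4Y": (22.99, 2.20),
    "ACET_PROP": (4.17, 0.40),
}


@dataclasses.dataclass
class EffectSpec:
    """Planted effect for one phenotype."""

    n_direct_asvs: int = 8
    effect_size_r: float = 0.3  # target |Pearson r| on the CSS-log2 scale
    noise_sd: float = 0.75  # phenotype noise relative to the unit-variance driver


@dataclasses.dataclass
class SimulationConfig:
    n_samples: int = 56
    n_asvs: int = 350
    n_families: int = 25
    library_size_log_mean: float = 9.9  # ~20k reads
    library_size_log_sd: float = 0.35
    dirichlet_concentration: float = 0.3
    sparsity_target: float = 0.55
    effects: dict[str, EffectSpec] = dataclasses.field(
        default_factory=lambda: {p: EffectSpec() for p in PHENOTYPES})
    n_mediated_asvs: int = 6
    phenotype_correlation: float = 0.5  # CH4Y-ACET_PROP target
    asv_dispersion: float = 1.0  # SD of per-sample latent log-abundance noise
    phenotype_targets: dict[str, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_PHENOTYPE_TARGETS))
    seed: int = 0

    def validate(self) -> None:
        errors = []
        if self.n_samples < 8:
            errors.append("n_samples must be >= 8")
        if self.n_asvs < 10:
            errors.append("n_asvs must be >= 10")
        if not 1 <= self.n_families <= self.n_asvs:
            errors.append("n_families must lie in [1, n_asvs]")
        if not 0 <= self.sparsity_target < 1:
            errors.append("sparsity_target must lie in [0, 1)")
        if self.dirichlet_concentration <= 0:
            errors.append("dirichlet_concentration must be positive")
        n_direct = sum(e.n_direct_asvs for e in self.effects.values())
        if n_direct + self.n_mediated_asvs > self.n_asvs:
            errors.append("direct + mediated ASVs exceed n_asvs")
        for name, eff in self.effects.items():
            if not 0 < eff.effect_size_r < 1:
                errors.append(f"{name}: effect_size_r must lie in (0, 1)")
            if eff.noise_sd < 0:
                errors.append(f"{name}: noise_sd must be non-negative")
        if errors:
            raise ValueError("invalid simulation config: " + "; ".join(errors))


@dataclasses.dataclass
class TruthSet:
    """Planted ground truth for recovery tests."""

    direct: dict[str, list[tuple[str, float]]]  # phenotype -> (asv_id, signed beta)
    mediated: list[tuple[str, str]]  # (mediated asv_id, mediator asv_id)
    family_of: dict[str, str]
    enriched_family: str
    seed: int

    def direct_ids(self, phenotype: str) -> list[str]:
        return [a for a, _ in self.direct[phenotype]]

    def all_direct_ids(self) -> set[str]:
        return {a for rows in self.direct.values() for a, _ in rows}

    def to_dict(self) -> dict:
        return {
            "direct": {p: [[a, b] for a, b in rows] for p, rows in self.direct.items()},
            "mediated": [[a, m] for a, m in self.mediated],
            "family_of": self.family_of,
            "enriched_family": self.enriched_family,
            "seed": self.seed,
        }


def _zipf_weights(n: int, exponent: float = 1.0) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** exponent
    return w / w.sum()


def _solve_log_spread(base_dev: np.ndarray, noise: np.ndarray,
                      depths: np.ndarray, target: float) -> float:
    """Scale factor for the base log-abundance deviations such that the
    expected zero fraction of the multinomial counts matches ``target``.

    The expected zero fraction is evaluated as mean_ij exp(-L_j p_ij)
    over the realised compositions; it increases with the spread, so a
    simple bisection suffices.
    """

    def expected_zero(sigma: float) -> float:
        x = sigma * base_dev[:, None] + noise
        w = np.exp(x - x.max(axis=0, keepdims=True))
        p = w / w.sum(axis=0, keepdims=True)
        return float(np.mean(np.exp(-depths[None, :] * p)))

    lo, hi = 0.05, 16.0
    if expected_zero(hi) < target:
        raise ValueError(f"sparsity_target={target} infeasible for this configuration")
    if expected_zero(lo) > target:
        return lo
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if expected_zero(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate(config: SimulationConfig) -> tuple[CountMatrix, TaxonomyTable,
                                                PhenotypeTable, TruthSet]:
    """Generate (counts, taxonomy, phenotypes, truth); deterministic given
    ``config.seed`` (a single random stream drives every draw)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m = config.n_asvs, config.n_samples
    asv_ids = [f"ASV_{i + 1:04d}" for i in range(n)]
    sample_ids = [f"S{j + 1:03d}" for j in range(m)]

    # --- taxonomy: Zipf-distributed family labels, ~5% unclassified ---
    n_fam = min(config.n_families, len(_FAMILY_POOL))
    families = _FAMILY_POOL[:n_fam]
    fam_idx = rng.choice(n_fam, size=n, p=_zipf_weights(n_fam))
    unclassified = rng.random(n) < 0.05
    family_of = {
        asv_ids[i]: ("" if unclassified[i] else families[fam_idx[i]])
        for i in range(n)
    }

    # --- compositional base and latent log abundances ---
    base = rng.dirichlet(np.full(n, config.dirichlet_concentration))
    base = np.maximum(base, 1e-12)
    base_dev = np.log(base) - np.log(base).mean()
    base_dev = base_dev / base_dev.std()
    noise = config.asv_dispersion * rng.standard_normal((n, m))
    depths = np.maximum(
        rng.lognormal(config.library_size_log_mean, config.library_size_log_sd, size=m),
        100.0,
    ).astype(np.int64)
    sigma = _solve_log_spread(base_dev, noise, depths.astype(float),
                              config.sparsity_target)
    mu = sigma * base_dev

    # --- latent phenotype drivers (unit variance, correlated CH4Y/ACET_PROP) ---
    a = {p: 1.0 / np.sqrt(1.0 + config.effects[p].noise_sd ** 2) for p in PHENOTYPES}
    rho_s = config.phenotype_correlation / (a["CH4Y"] * a["ACET_PROP"])
    rho_s = float(np.clip(rho_s, -0.99, 0.99))
    z = rng.standard_normal((m, 3))
    s = np.empty((m, 3))
    s[:, 0] = z[:, 0]  # EFF driver
    s[:, 1] = z[:, 1]  # CH4Y driver
    s[:, 2] = rho_s * z[:, 1] + np.sqrt(1.0 - rho_s ** 2) * z[:, 2]  # ACET_PROP
    drivers = {p: s[:, i] for i, p in enumerate(PHENOTYPES)}

    # --- choose direct / mediated ASVs among prevalent, classified taxa ---
    eligible = [i for i in np.argsort(mu)[::-1][: max(n // 2, 30)]
                if not unclassified[i]]
    enriched_family = families[min(3, n_fam - 1)]
    enriched_members = [i for i in eligible if families[fam_idx[i]] == enriched_family]
    other_members = [i for i in eligible if families[fam_idx[i]] != enriched_family]
    rng.shuffle(enriched_members)
    rng.shuffle(other_members)
    x = mu[:, None] + noise
    truth_direct: dict[str, list[tuple[str, float]]] = {p: [] for p in PHENOTYPES}
    used: list[int] = []
    tau = config.asv_dispersion
    for p in PHENOTYPES:
        eff = config.effects[p]
        n_enr = min(eff.n_direct_asvs // 2, len(enriched_members))
        chosen = [enriched_members.pop() for _ in range(n_enr)]
        while len(chosen) < eff.n_direct_asvs:
            if not other_members:
                raise ValueError("not enough eligible ASVs for the requested effects")
            chosen.append(other_members.pop())
        g = eff.effect_size_r / (a[p] * ATTENUATION)
        if not g < 1:
            raise ValueError(f"{p}: effect_size_r={eff.effect_size_r} too large "
                             "to realise after attenuation")
        beta_mag = tau * g / np.sqrt(1.0 - g ** 2)
        for i in chosen:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            x[i] += sign * beta_mag * drivers[p]
            truth_direct[p].append((asv_ids[i], float(sign * beta_mag)))
            used.append(i)

    mediated: list[tuple[str, str]] = []
    all_direct = [(p, i) for p in PHENOTYPES
                  for i, (aid, _) in enumerate(truth_direct[p])]
    pool = [i for i in (enriched_members + other_members) if i not in used]
    c_med = 0.65  # target latent correlation between a mediated ASV and its mediator
    direct_index = {aid: idx for idx, aid in enumerate(asv_ids)}
    flat_direct_ids = [aid for p in PHENOTYPES for aid, _ in truth_direct[p]]
    for k in range(config.n_mediated_asvs):
        if not pool:
            break
        i = pool.pop()
        mediator_id = flat_direct_ids[k % len(flat_direct_ids)]
        j = direct_index[mediator_id]
        dev = x[j] - mu[j]
        lam = (c_med / np.sqrt(1.0 - c_med ** 2)) * tau / dev.std()
        x[i] = mu[i] + lam * dev + tau * rng.standard_normal(m)
        mediated.append((asv_ids[i], mediator_id))

    # --- multinomial count sampling ---
    w = np.exp(x - x.max(axis=0, keepdims=True))
    probs = w / w.sum(axis=0, keepdims=True)
    counts = np.empty((n, m), dtype=np.int64)
    for j in range(m):
        counts[:, j] = rng.multinomial(depths[j], probs[:, j])
    count_matrix = CountMatrix(asv_ids, sample_ids, counts)

    # --- phenotypes: driver + noise, rescaled to target mean/SD ---
    pheno = {}
    for p in PHENOTYPES:
        raw = drivers[p] + config.effects[p].noise_sd * rng.standard_normal(m)
        raw = (raw - raw.mean()) / raw.std()
        mean, sd = config.phenotype_targets[p]
        pheno[p] = mean + sd * raw
    phenotypes = PhenotypeTable(
        sample_ids, pd.DataFrame(pheno, index=sample_ids))

    taxonomy = _build_taxonomy(asv_ids, family_of, rng)
    truth = TruthSet(direct=truth_direct, mediated=mediated,
                     family_of=family_of, enriched_family=enriched_family,
                     seed=config.seed)
    return count_matrix, taxonomy, phenotypes, truth


def _build_taxonomy(asv_ids: list[str], family_of: dict[str, str],
                    rng: np.random.Generator) -> TaxonomyTable:
    lineages = {}
    for aid in asv_ids:
        family = family_of[aid]
        if family == "":
            lineage = "d__Bacteria; p__Bacillota; c__Clostridia; o__; f__; g__"
        else:
            phylum = "Bacteroidota" if family in _BACTEROIDOTA else "Bacillota"
            cls = "Bacteroidia" if phylum == "Bacteroidota" else "Clostridia"
            order = "Bacteroidales" if phylum == "Bacteroidota" else "Oscillospirales"
            stem = family[:-5] if family.endswith("aceae") else family
            genus = stem if rng.random() < 0.7 else ""
            lineage = (f"d__Bacteria; p__{phylum}; c__{cls}; o__{order}; "
                       f"f__{family}; g__{genus}")
        lineages[aid] = parse_lineage(lineage)
    return TaxonomyTable(list(asv_ids), lineages)


def degenerate_fixture(name: str):
    """Hand-sized deterministic fixtures for unit tests.

    ``tiny_counts``: a 5-feature x 6-sample count table.
    ``collinear_pair``: four features, two of them identical.
    ``mediated_trio``: three features where z drives both x and y, so
    the x-y marginal correlation is high but vanishes given z.
    """
    if name == "tiny_counts":
        counts = np.array([
            [5, 0, 3, 1, 0, 2],
            [0, 7, 0, 0, 4, 0],
            [1, 1, 1, 1, 1, 1],
            [0, 0, 0, 9, 0, 0],
            [12, 3, 5, 2, 8, 4],
        ])
        return CountMatrix([f"ASV_{i}" for i in range(1, 6)],
                           [f"S{j}" for j in range(1, 7)], counts)
    if name == "collinear_pair":
        counts = np.array([
            [4, 2, 8, 6, 1, 3],
            [4, 2, 8, 6, 1, 3],
            [1, 0, 2, 5, 9, 2],
            [0, 3, 1, 0, 2, 7],
        ])
        return CountMatrix(["dup_a", "dup_b", "other_1", "other_2"],
                           [f"S{j}" for j in range(1, 7)], counts)
    if name == "mediated_trio":
        # x and y are independent noisy readouts of z: their marginal
        # correlation (~0.22) vanishes once z is partialled out (~0.03),
        # and the PCIT trio scan removes exactly the x-y edge.  Note the
        # mediator correlations must stay below ~0.58: the PCIT tolerance
        # cannot exceed ~2/3, so a mediated pair with a stronger marginal
        # correlation would be retained by construction.
        x = np.array([15, 11, 9, 11, 5, 12, 0, 0, 17, 0, 29, 7], dtype=np.int64)
        y = np.array([19, 11, 0, 1, 14, 0, 0, 16, 12, 9, 13, 0], dtype=np.int64)
        z = np.array([10, 10, 2, 3, 6, 2, 10, 3, 15, 11, 15, 7], dtype=np.int64)
        counts = np.vstack([x, y, z])
        return CountMatrix(["x", "y", "z"], [f"S{j}" for j in range(1, 13)], counts)
    raise ValueError(f"unknown fixture {name!r}")
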