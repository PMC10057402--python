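"""Seeded synthetic-data generator emulating the in vivo study design.

The generator replaces the animal experiment: 12-or-fewer simulated
exposures, doses {0, 6, 18, 54} ug/mouse, 8 vehicle-control and 5
treated replicates per dose, log2 expression with additive Gaussian
noise. Dose-responsive genes follow one of the seven benchmark-dose
model families, parameterized so that the true BMD is exactly the dose
at which the mean curve departs from background by
``bmr_factor * noise_sd`` — the same definition the BMD engine
estimates, which keeps planted truth and estimator consistent.

Independent child RNG streams (derived from ``seed``) drive expression
noise, responsive-gene assignment, bioassay draws, module draws and the
signature, so the three generators are individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneSetCollection

MODEL_FAMILIES = ("Exp2", "Exp3", "Exp4", "Exp5", "Linear", "Poly2", "Power")

# child-stream tags
_STREAM_NOISE = 0
_STREAM_TRUTH = 1
_STREAM_BIOASSAY = 2
_STREAM_MODULES = 3
_STREAM_SIGNATURE = 4
_STREAM_CHANNEL = 5


@dataclass
class SimConfig:
    """Configuration of one synthetic experiment.

    Defaults mirror the transcriptomic design of the study being
    emulated: doses 0/6/18/54 ug/mouse, n=8 controls, n=5 per treated
    group, log2-scale residual SD 0.2.
    """

    n_genes: int = 2000
    n_responsive: int = 200
    doses: tuple = (0.0, 6.0, 18.0, 54.0)
    n_control: int = 8
    n_treated: int = 5
    noise_sd: float = 0.2
    model_family_weights: dict = field(
        default_factory=lambda: {m: 1.0 for m in MODEL_FAMILIES}
    )
    true_bmd_range: tuple = (1.0, 54.0)
    n_modules: int = 10
    module_size_range: tuple = (10, 40)
    signature_size: int = 17
    seed: int = 0
    # exposure -> multiplicative scale applied to every true BMD of that
    # exposure (lower scale = more potent material)
    exposures: dict = field(default_factory=lambda: {"CNT-A": 1.0})
    bmr_factor: float = 1.349
    batch_sd: float = 0.0
    modules_disjoint: bool = False
    planted_enriched_modules: int = 0
    # bioassay effect sizes (top-dose multiplier on the group mean)
    neutrophil_baseline: float = 5000.0
    neutrophil_dispersion: float = 5.0
    taildna_baseline: float = 4.2
    bioassay_multiplier: float = 10.0
    bioassay_multipliers: Optional[dict] = None
    taildna_multiplier: float = 1.5
    # pro-fibrotic signature planting
    signature_separation: float = 2.0
    signature_noise_sd: float = 1.0
    profibrotic_exposure: Optional[str] = None  # default: first exposure, top dose

    def __post_init__(self) -> None:
        self.doses = tuple(float(d) for d in self.doses)
        for name in ("n_genes", "n_control", "n_treated", "n_modules", "signature_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"invalid SimConfig.{name}: must be >= 1")
        if not 0 <= self.n_responsive <= self.n_genes:
            raise ValueError("invalid SimConfig.n_responsive: must be in [0, n_genes]")
        if list(self.doses) != sorted(self.doses) or self.doses[0] != 0.0:
            raise ValueError("invalid SimConfig.doses: must be ascending and start at 0")
        if len(self.doses) < 2 or len(set(self.doses)) != len(self.doses):
            raise ValueError("invalid SimConfig.doses: need >= 2 distinct levels")
        if self.noise_sd < 0:
            raise ValueError("invalid SimConfig.noise_sd: must be >= 0")
        lo, hi = self.true_bmd_range
        if not (0 < lo <= hi <= max(self.doses)):
            raise ValueError("invalid SimConfig.true_bmd_range: need 0 < low <= high <= max dose")
        if not self.model_family_weights:
            raise ValueError("invalid SimConfig.model_family_weights: empty")
        unknown = set(self.model_family_weights) - set(MODEL_FAMILIES)
        if unknown:
            raise ValueError(f"invalid SimConfig.model_family_weights: unknown models {sorted(unknown)}")
        if any(w < 0 for w in self.model_family_weights.values()) or (
            sum(self.model_family_weights.values()) <= 0
        ):
            raise ValueError("invalid SimConfig.model_family_weights: need non-negative weights summing > 0")
        smin, smax = self.module_size_range
        if not (1 <= smin <= smax):
            raise ValueError("invalid SimConfig.module_size_range: need 1 <= min <= max")
        if not self.exposures:
            raise ValueError("invalid SimConfig.exposures: empty")
        if self.signature_size < 2:
            raise ValueError("invalid SimConfig.signature_size: must be >= 2")

    @property
    def max_dose(self) -> float:
        return max(self.doses)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), stream])


@dataclass
class SimTruth:
    """Planted ground truth of one synthetic experiment."""

    responsive_gene_ids: list
    models: dict  # gene -> model family name
    params: dict  # gene -> parameter dict (direction, baseline, ...)
    true_bmd: dict  # exposure -> gene -> true BMD (dose units)
    module_membership: dict  # gene -> list of module names
    potency_order: list  # exposures, most potent (lowest BMD scale) first
    signature_genes: list
    signature_directions: dict  # gene -> +1/-1 expected regulation
    signature_class: dict  # "exposure@dose" -> class label

    def to_dict(self) -> dict:
        return {
            "responsive_gene_ids": list(self.responsive_gene_ids),
            "models": self.models,
            "params": self.params,
            "true_bmd": self.true_bmd,
            "module_membership": self.module_membership,
            "potency_order": self.potency_order,
            "signature_genes": list(self.signature_genes),
            "signature_directions": self.signature_directions,
            "signature_class": self.signature_class,
        }


def _gene_ids(config: SimConfig) -> list[str]:
    width = max(4, len(str(config.n_genes)))
    return [f"g{i:0{width}d}" for i in range(1, config.n_genes + 1)]


def _responsive_ids(config: SimConfig) -> list[str]:
    genes = _gene_ids(config)
    rng = config.rng(_STREAM_TRUTH)
    idx = rng.permutation(config.n_genes)[: config.n_responsive]
    return [genes[i] for i in sorted(idx)]


def _signature_genes(config: SimConfig) -> tuple[list[str], dict[str, int]]:
    """Signature panel drawn from the non-responsive pool (kept apart
    from the dose-responsive genes so the two planted signals do not
    interfere)."""
    genes = _gene_ids(config)
    responsive = set(_responsive_ids(config))
    pool = [g for g in genes if g not in responsive]
    if len(pool) < config.signature_size:
        raise ValueError("invalid SimConfig.signature_size: exceeds non-responsive gene pool")
    rng = config.rng(_STREAM_SIGNATURE)
    chosen = sorted(rng.choice(len(pool), size=config.signature_size, replace=False))
    panel = [pool[i] for i in chosen]
    dirs = {g: int(d) for g, d in zip(panel, rng.choice([1, -1], size=len(panel)))}
    return panel, dirs


def signature_shift(config: SimConfig) -> pd.Series:
    """Per-gene log2 shift placing the planted pro-fibrotic condition at
    the pro-fibrotic class centroid.

    ``signature_separation`` counts within-class SDs between each class
    centroid and the class midpoint, so the centroids sit
    ``2 * separation`` SDs apart along the signature direction."""
    panel, dirs = _signature_genes(config)
    u = np.array([dirs[g] for g in panel], float)
    u /= np.linalg.norm(u)
    shift = 2.0 * config.signature_separation * config.signature_noise_sd * u
    return pd.Series(shift, index=panel)


def _draw_model_params(config: SimConfig, rng: np.random.Generator, model: str) -> dict:
    """Parameters for one responsive gene, anchored so that
    |mu(bmd) - mu(0)| = bmr_factor * noise_sd exactly."""
    a = rng.uniform(6.0, 12.0)
    s = int(rng.choice([1, -1]))
    lo, hi = config.true_bmd_range
    bmd = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    amp = config.bmr_factor * config.noise_sd
    # cap the shape for unbounded-growth families so the top-dose effect
    # stays physical (<= ~30x the benchmark response on the log2 scale)
    span = config.max_dose / bmd
    g_hi = 4.0 if span <= 1.5 else float(min(4.0, max(1.0, np.log(30.0) / np.log(span))))
    g_draw = rng.uniform(1.0, 4.0)
    g = float(1.0 + (g_hi - 1.0) * (g_draw - 1.0) / 3.0) if model in ("Power", "Exp2", "Exp3") else g_draw
    p: dict = {"model": model, "a": a, "direction": s, "bmd": bmd}
    if model == "Linear":
        p["b"] = s * amp / bmd
    elif model == "Poly2":
        t = rng.uniform(0.2, 0.8)
        if span * span > 30.0:  # cap the quadratic share of the top-dose effect
            t *= max(0.0, (30.0 - span) / (span * span - span))
        p["b"] = s * amp * (1 - t) / bmd
        p["c"] = s * amp * t / bmd**2
    elif model == "Power":
        p["g"] = g
        p["b"] = s * amp / bmd**g
    elif model in ("Exp2", "Exp3"):
        if s > 0:
            core = np.log1p(amp / a)
        else:
            core = -np.log1p(-min(amp / a, 0.99))
        gg = 1.0 if model == "Exp2" else g
        p["g"] = gg
        p["b"] = core ** (1.0 / gg) / bmd
    elif model in ("Exp4", "Exp5"):
        plateau = rng.uniform(1.5, 4.0) * amp  # asymptotic total effect
        p["c"] = 1.0 + s * plateau / a
        gg = 1.0 if model == "Exp4" else g
        p["g"] = gg
        p["b"] = (-np.log1p(-amp / plateau)) ** (1.0 / gg) / bmd
    else:  # pragma: no cover
        raise ValueError(f"unknown model family: {model}")
    return p


def mean_curve(params: dict, dose: np.ndarray) -> np.ndarray:
    """Evaluate a planted mean curve at the given doses."""
    d = np.asarray(dose, float)
    m, a = params["model"], params["a"]
    if m == "Linear":
        return a + params["b"] * d
    if m == "Poly2":
        return a + params["b"] * d + params["c"] * d**2
    if m == "Power":
        return a + params["b"] * d ** params["g"]
    if m in ("Exp2", "Exp3"):
        s = params["direction"]
        return a * np.exp(s * (params["b"] * d) ** params["g"])
    if m in ("Exp4", "Exp5"):
        c = params["c"]
        return a * (c - (c - 1.0) * np.exp(-((params["b"] * d) ** params["g"])))
    raise ValueError(f"unknown model family: {m}")


def _sample_frame(config: SimConfig) -> pd.DataFrame:
    rows = []
    for exp in config.exposures:
        for r in range(1, config.n_control + 1):
            rows.append((f"{exp}_c{r:02d}", exp, 0.0, r))
        for dose in config.doses[1:]:
            for r in range(1, config.n_treated + 1):
                rows.append((f"{exp}_d{dose:g}_r{r:02d}", exp, dose, r))
    df = pd.DataFrame(rows, columns=["sample_id", "exposure", "dose", "replicate"])
    return df.set_index("sample_id")


def simulate_experiment(config: SimConfig) -> tuple[ExpressionMatrix, SimTruth]:
    """Generate a log2 expression matrix plus its planted truth.

    Responsive genes follow their drawn model-family mean curve (per
    exposure, with the exposure's BMD scale applied); all genes get
    additive Normal(0, noise_sd) residuals. One exposure-dose condition
    carries the planted pro-fibrotic signature shift.
    """
    genes = _gene_ids(config)
    samples = _sample_frame(config)
    responsive = _responsive_ids(config)
    truth_rng = config.rng(_STREAM_TRUTH)
    truth_rng.permutation(config.n_genes)  # advance past the responsive draw

    names = sorted(config.model_family_weights)
    w = np.array([config.model_family_weights[n] for n in names], float)
    w /= w.sum()

    models, params = {}, {}
    for gid in responsive:
        model = names[int(truth_rng.choice(len(names), p=w))]
        models[gid] = model
        params[gid] = _draw_model_params(config, truth_rng, model)

    noise_rng = config.rng(_STREAM_NOISE)
    values = noise_rng.normal(0.0, config.noise_sd, size=(config.n_genes, len(samples)))
    baseline = noise_rng.uniform(6.0, 12.0, size=config.n_genes)
    values += baseline[:, None]
    values = pd.DataFrame(values, index=genes, columns=samples.index)

    dose_by_col = samples["dose"].to_numpy(float)
    exp_by_col = samples["exposure"].to_numpy()
    gene_pos = {g: i for i, g in enumerate(genes)}
    true_bmd: dict = {e: {} for e in config.exposures}
    for gid in responsive:
        p = params[gid]
        row = np.full(len(samples), p["a"])
        for exp, scale in config.exposures.items():
            cols = exp_by_col == exp
            # scaling doses by 1/scale scales the gene's BMD by `scale`
            row[cols] = mean_curve(p, dose_by_col[cols] / scale)
            true_bmd[exp][gid] = p["bmd"] * scale
        # replace the flat baseline with the planted curve, keeping the noise
        values.loc[gid] += row - baseline[gene_pos[gid]]

    if config.batch_sd > 0:
        batch = {e: noise_rng.normal(0.0, config.batch_sd) for e in config.exposures}
        values += np.array([batch[e] for e in exp_by_col])[None, :]

    # plant the pro-fibrotic signature on one exposure-dose condition
    panel, dirs = _signature_genes(config)
    pro_exp = config.profibrotic_exposure or next(iter(config.exposures))
    if pro_exp not in config.exposures:
        raise ValueError(f"invalid SimConfig.profibrotic_exposure: {pro_exp!r} not among exposures")
    pro_dose = config.max_dose
    shift = signature_shift(config)
    pro_cols = samples.index[(exp_by_col == pro_exp) & (dose_by_col == pro_dose)]
    values.loc[panel, pro_cols] = values.loc[panel, pro_cols].add(shift, axis=0)

    signature_class = {
        f"{e}@{d:g}": (
            "pro-fibrotic" if (e == pro_exp and d == pro_dose) else "non-fibrotic"
        )
        for e in config.exposures
        for d in config.doses[1:]
    }

    membership = _module_membership(config)
    order = sorted(config.exposures, key=lambda e: (config.exposures[e], e))
    truth = SimTruth(
        responsive_gene_ids=list(responsive),
        models=models,
        params=params,
        true_bmd=true_bmd,
        module_membership=membership,
        potency_order=order,
        signature_genes=panel,
        signature_directions=dirs,
        signature_class=signature_class,
    )
    return ExpressionMatrix(values, samples), truth


def _module_draw(config: SimConfig) -> dict[str, list[str]]:
    genes = _gene_ids(config)
    rng = config.rng(_STREAM_MODULES)
    smin, smax = config.module_size_range
    sizes = rng.integers(smin, smax + 1, size=config.n_modules)
    sizes = np.minimum(sizes, config.n_genes)  # sets cannot exceed the universe
    if config.modules_disjoint and sizes.sum() > config.n_genes:
        raise ValueError(
            "requested disjoint modules exceed the gene universe "
            f"({sizes.sum()} > {config.n_genes})"
        )
    responsive = _responsive_ids(config)
    pool = list(rng.permutation(genes))
    sets: dict[str, list[str]] = {}
    for k, size in enumerate(sizes, start=1):
        name = f"module{k:02d}"
        if k <= config.planted_enriched_modules:
            if len(responsive) < size:
                raise ValueError(
                    "planted_enriched_modules: module size exceeds responsive pool"
                )
            idx = rng.choice(len(responsive), size=size, replace=False)
            sets[name] = sorted(responsive[i] for i in idx)
            continue
        if len(pool) >= size:
            sets[name], pool = sorted(pool[:size]), pool[size:]
        else:  # universe exhausted: fall back to sampling with reuse
            idx = rng.choice(config.n_genes, size=size, replace=False)
            sets[name] = sorted(genes[i] for i in idx)
    return sets


def _module_membership(config: SimConfig) -> dict[str, list[str]]:
    member: dict[str, list[str]] = {}
    for name, gs in _module_draw(config).items():
        for g in gs:
            member.setdefault(g, []).append(name)
    return member


def make_gene_sets(config: SimConfig) -> GeneSetCollection:
    """Module gene sets plus the designated ``signature`` set.

    Modules are drawn without replacement while the gene universe
    lasts; with ``modules_disjoint`` set, exhausting the universe is an
    error instead. The first ``planted_enriched_modules`` modules are
    drawn entirely from the responsive pool (for power studies of the
    enrichment stage).
    """
    sets = _module_draw(config)
    panel, dirs = _signature_genes(config)
    sets["signature"] = panel
    return GeneSetCollection(sets, directions={"signature": dirs}, description="synthetic")


def simulate_bioassay(config: SimConfig) -> pd.DataFrame:
    """Per-animal bioassay records: BALF neutrophil counts (negative
    binomial, overdispersed) and comet %% tail DNA (gamma, clipped to
    [0, 100]) per exposure and dose.

    The group mean rises geometrically with dose up to the configured
    top-dose multiplier (per-exposure overrides via
    ``bioassay_multipliers``).
    """
    rng = config.rng(_STREAM_BIOASSAY)
    disp = config.neutrophil_dispersion
    rows = []
    for exp in config.exposures:
        mult = (config.bioassay_multipliers or {}).get(exp, config.bioassay_multiplier)
        for dose in config.doses:
            n = config.n_control if dose == 0 else config.n_treated
            frac = dose / config.max_dose
            neut_mean = config.neutrophil_baseline * mult**frac
            tail_mean = config.taildna_baseline * config.taildna_multiplier**frac
            p_nb = disp / (disp + neut_mean)
            counts = rng.negative_binomial(disp, p_nb, size=n)
            tails = np.clip(rng.gamma(8.0, tail_mean / 8.0, size=n), 0.0, 100.0)
            for i in range(n):
                rows.append((exp, dose, i + 1, int(counts[i]), float(tails[i])))
    return pd.DataFrame(
        rows, columns=["exposure", "dose", "animal", "neutrophils", "tail_dna"]
    )


def simulate_two_channel(
    em: ExpressionMatrix, bias_amplitude: float = 0.3, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Back-transform a log2 matrix into two-channel intensities with an
    intensity-dependent dye bias, for exercising LOWESS normalization.

    The sample channel (Cy5-like, R) carries the expression values
    against a common reference (row means, G); the planted bias adds
    ``bias_amplitude * (A - mean(A))`` to each log-ratio.
    """
    rng = np.random.default_rng(seed)
    x = em.values.to_numpy(float)
    ref = x.mean(axis=1, keepdims=True) + rng.normal(0.0, 0.05, size=(x.shape[0], 1))
    a = (x + ref) / 2.0
    m = x - ref
    m_biased = m + bias_amplitude * (a - a.mean(axis=0, keepdims=True))
    red = np.power(2.0, a + m_biased / 2.0)
    green = np.power(2.0, a - m_biased / 2.0)
    red = pd.DataFrame(red, index=em.values.index, columns=em.values.columns)
    green = pd.DataFrame(green, index=em.values.index, columns=em.values.columns)
    return red, green


def simulate_compendium(
    panel: list[str],
    directions: dict[str, int],
    n_pro: int = 60,
    n_non: int = 60,
    separation: float = 2.0,
    noise_sd: float = 1.0,
    residual_frac: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Synthetic reference compendium for the signature classifier.

    Each condition's fold-change vector follows a severity-factor
    model, mirroring how real compendia vary chiefly along a response
    gradient: FC = s * noise_sd * u + residual, where u is the unit
    signature direction, the scalar severity s has within-class SD 1
    with class means 0 (non-fibrotic) and ``2 * separation``
    (pro-fibrotic, i.e. each centroid ``separation`` SDs from the class
    midpoint), and the isotropic residual has SD
    ``residual_frac * noise_sd`` per gene.
    """
    rng = np.random.default_rng(seed)
    u = np.array([directions[g] for g in panel], float)
    u /= np.linalg.norm(u)
    sev = np.concatenate(
        [rng.normal(2.0 * separation, 1.0, n_pro), rng.normal(0.0, 1.0, n_non)]
    )
    fc_values = np.outer(sev * noise_sd, u) + rng.normal(
        0.0, residual_frac * noise_sd, size=(n_pro + n_non, len(panel))
    )
    fc = pd.DataFrame(
        fc_values,
        index=[f"pro{i+1:02d}" for i in range(n_pro)]
        + [f"non{i+1:02d}" for i in range(n_non)],
        columns=panel,
    )
    labels = pd.Series(
        ["pro-fibrotic"] * n_pro + ["non-fibrotic"] * n_non, index=fc.index, name="label"
    )
    return fc, labels


def make_compendium(config: SimConfig, n_pro: int = 60, n_non: int = 60) -> tuple[pd.DataFrame, pd.Series]:
    """Compendium matched to the experiment's planted signature panel."""
    panel, dirs = _signature_genes(config)
    return simulate_compendium(
        panel,
        dirs,
        n_pro=n_pro,
        n_non=n_non,
        separation=config.signature_separation,
        noise_sd=config.signature_noise_sd,
        seed=int(config.seed) % (2**31) + 7,
    )
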