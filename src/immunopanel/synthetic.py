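"""Synthetic bulk-expression cohorts with the statistical structure the
panel analysis assumes.

Each sample carries a latent immune-infiltration factor L (log2-scale,
arbitrary units).  Panel genes load on L — activation genes always, checkpoint
genes through a condition-dependent coupling that is stronger in tumors than
in normals, which is what makes the activation-checkpoint correlation higher
in tumors.  Control genes are generated independently of L and of response;
a small fraction of the remaining background genes is weakly loaded on L to
mimic transcriptome bleed-through.  Log2 expression is Gaussian around a
per-gene baseline and exponentiated, so every value is positive and
per-sample medians are positive by construction.

Two imperfect readouts of L accompany each cohort: ``true_infiltration``
(L plus measurement noise, standing in for in-silico infiltration
estimators) and ``pathology_score`` (L binned into cohort quartiles 0-3
with ordinal label noise, emulating a pathologist's lymphocyte-infiltration
grading).

The ICB cohort is all-tumor and on-treatment, split across anti-PD-1 and
anti-CTLA-4 arms; responders have their latent mean shifted upward by
``responder_effect`` (log2-latent units; the default 1.5 is three
within-class latent SDs), which elevates every panel gene through its
loading while leaving control genes untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import ExpressionMatrix, validate_metadata
from .panels import ACTIVATION_GENES, CHECKPOINT_GENES, CONTROL_GENES


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; the defaults are the simulated study conditions.

    All latent-scale quantities are in log2 expression units.
    """

    n_tissues: int = 3
    samples_per_group: int = 100  # per condition (tissue cohort) / per arm (ICB)
    n_background_genes: int = 2000
    infiltration_mean_tumor: float = 1.5
    infiltration_mean_normal: float = 0.5
    infiltration_sd: float = 0.5
    tissue_offset_sd: float = 0.2  # per-tissue shift of the latent mean
    panel_loading_range: tuple[float, float] = (0.8, 1.2)
    checkpoint_coupling_tumor: float = 1.0
    checkpoint_coupling_normal: float = 0.3
    noise_sd: float = 0.3
    gene_baseline_mean: float = 3.0
    gene_baseline_sd: float = 1.0
    background_loaded_fraction: float = 0.05
    background_loading: float = 0.1
    # mean latent shift of responders, log2-latent units (3 SD at defaults)
    responder_effect: float = 1.5
    responder_fraction: float = 0.4
    n_responders: int | None = None  # exact counts override responder_fraction
    n_nonresponders: int | None = None
    drop_btla: bool = False
    pathology_flip_prob: float = 0.15
    infiltration_readout_sd: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.samples_per_group < 2:
            raise ValidationError("samples_per_group must be >= 2")
        if self.n_tissues < 1:
            raise ValidationError("n_tissues must be >= 1")
        for name in ("infiltration_sd", "noise_sd", "gene_baseline_sd"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if not 0 < self.responder_fraction < 1:
            raise ValidationError("responder_fraction must be in (0, 1)")
        if not 0 <= self.background_loaded_fraction <= 1:
            raise ValidationError("background_loaded_fraction must be in [0, 1]")
        lo, hi = self.panel_loading_range
        if not (0 < lo <= hi):
            raise ValidationError("panel_loading_range must be 0 < lo <= hi")
        if (self.n_responders is None) != (self.n_nonresponders is None):
            raise ValidationError(
                "n_responders and n_nonresponders must be set together"
            )
        if self.n_responders is not None and (
            self.n_responders < 1 or self.n_nonresponders < 1
        ):
            raise ValidationError("exact response counts must be >= 1")


@dataclass
class SyntheticCohort:
    """A generated cohort: matrix + metadata + the generating truth."""

    matrix: ExpressionMatrix
    meta: pd.DataFrame
    config: CohortConfig
    truth: dict = field(default_factory=dict)


def _gene_table(config: CohortConfig, rng: np.random.Generator):
    """Gene symbols, baselines and latent loadings for one cohort."""
    lo, hi = config.panel_loading_range
    panel_genes = list(ACTIVATION_GENES) + list(CHECKPOINT_GENES)
    background = [f"BG{i:05d}" for i in range(1, config.n_background_genes + 1)]
    genes = panel_genes + list(CONTROL_GENES) + background
    baselines = rng.normal(
        config.gene_baseline_mean, config.gene_baseline_sd, size=len(genes)
    )
    loadings = np.zeros(len(genes))
    loadings[: len(panel_genes)] = rng.uniform(lo, hi, size=len(panel_genes))
    # control fixture genes stay unloaded; a fraction of background genes
    # picks up a weak loading to mimic transcriptome bleed-through
    n_bg = len(background)
    n_loaded = int(round(config.background_loaded_fraction * n_bg))
    if n_loaded:
        start = len(panel_genes) + len(CONTROL_GENES)
        idx = rng.choice(n_bg, size=n_loaded, replace=False) + start
        loadings[idx] = config.background_loading
    # condition-dependent coupling multiplies checkpoint-gene loadings only
    is_checkpoint = np.zeros(len(genes), dtype=bool)
    is_checkpoint[len(ACTIVATION_GENES): len(panel_genes)] = True
    return genes, baselines, loadings, is_checkpoint


def _expression(
    config: CohortConfig,
    rng: np.random.Generator,
    baselines: np.ndarray,
    loadings: np.ndarray,
    is_checkpoint: np.ndarray,
    latent: np.ndarray,
    coupling: np.ndarray,
) -> np.ndarray:
    """Linear-scale expression (genes x samples) from the latent factors."""
    eff = np.where(
        is_checkpoint[:, None], loadings[:, None] * coupling[None, :],
        loadings[:, None],
    )
    log_expr = (
        baselines[:, None]
        + eff * latent[None, :]
        + rng.normal(0.0, config.noise_sd, size=(len(baselines), len(latent)))
    )
    return np.exp2(log_expr)


def _readouts(config: CohortConfig, rng: np.random.Generator, latent: np.ndarray):
    """Noisy infiltration readout and quartile-binned ordinal pathology score."""
    infiltration = latent + rng.normal(
        0.0, config.infiltration_readout_sd, size=len(latent)
    )
    quartiles = np.quantile(latent, [0.25, 0.5, 0.75])
    score = np.digitize(latent, quartiles)
    flip = rng.random(len(latent)) < config.pathology_flip_prob
    direction = rng.choice([-1, 1], size=len(latent))
    score = np.clip(score + flip * direction, 0, 3)
    return infiltration, score.astype(int)


def generate_tissue_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Multi-tissue tumor + matched-normal cohort.

    Tumors have a higher mean latent infiltration and full checkpoint
    coupling; normals have a lower mean and weak coupling, so tumors show
    both higher panel scores and a tighter activation-checkpoint
    correlation.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, baselines, loadings, is_checkpoint = _gene_table(config, rng)
    tissue_offsets = rng.normal(0.0, config.tissue_offset_sd, size=config.n_tissues)

    latents, couplings, meta_rows, sample_ids = [], [], [], []
    for t in range(config.n_tissues):
        tissue = f"tissue{t + 1:02d}"
        for condition, mu, coup in (
            ("tumor", config.infiltration_mean_tumor, config.checkpoint_coupling_tumor),
            (
                "normal",
                config.infiltration_mean_normal,
                config.checkpoint_coupling_normal,
            ),
        ):
            latent = rng.normal(
                mu + tissue_offsets[t],
                config.infiltration_sd,
                size=config.samples_per_group,
            )
            for i, value in enumerate(latent):
                sample_ids.append(f"{tissue}_{condition}_{i + 1:03d}")
                meta_rows.append({"tissue": tissue, "condition": condition})
            latents.append(latent)
            couplings.append(np.full(config.samples_per_group, coup))
    latent = np.concatenate(latents)
    coupling = np.concatenate(couplings)

    values = _expression(
        config, rng, baselines, loadings, is_checkpoint, latent, coupling
    )
    infiltration, pathology = _readouts(config, rng, latent)
    meta = pd.DataFrame(meta_rows)
    meta.insert(0, "sample_id", sample_ids)
    meta["arm"] = "none"
    meta["response"] = "not-applicable"
    meta["pathology_score"] = pathology
    meta["true_infiltration"] = infiltration

    matrix = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=sample_ids))
    meta = validate_metadata(meta, matrix)
    truth = {
        "latent": pd.Series(latent, index=sample_ids),
        "loadings": pd.Series(loadings, index=genes),
        "tissue_offsets": tissue_offsets,
    }
    return SyntheticCohort(matrix=matrix, meta=meta, config=config, truth=truth)


def generate_icb_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """On-treatment melanoma-like ICB cohort with known response labels.

    Samples split across anti-PD-1 and anti-CTLA-4 arms.  Response labels
    are Bernoulli(``responder_fraction``) unless exact counts are given via
    ``n_responders``/``n_nonresponders``.  Responders' latent infiltration
    mean is shifted up by ``responder_effect`` (log2-latent units), which
    raises all panel genes through their loadings; control and background
    genes are independent of response.  ``drop_btla`` removes the BTLA row
    to reproduce a platform where that gene is unmeasured.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, baselines, loadings, is_checkpoint = _gene_table(config, rng)

    if config.n_responders is not None:
        n_total = config.n_responders + config.n_nonresponders
        responder = np.zeros(n_total, dtype=bool)
        responder[: config.n_responders] = True
        rng.shuffle(responder)
    else:
        n_total = 2 * config.samples_per_group
        responder = rng.random(n_total) < config.responder_fraction
    arms = np.where(np.arange(n_total) % 2 == 0, "anti-PD-1", "anti-CTLA-4")
    rng.shuffle(arms)

    mu = config.infiltration_mean_tumor + config.responder_effect * responder
    latent = rng.normal(mu, config.infiltration_sd)
    coupling = np.full(n_total, config.checkpoint_coupling_tumor)
    values = _expression(
        config, rng, baselines, loadings, is_checkpoint, latent, coupling
    )
    infiltration, pathology = _readouts(config, rng, latent)

    sample_ids = [f"icb_{i + 1:04d}" for i in range(n_total)]
    df = pd.DataFrame(values, index=genes, columns=sample_ids)
    if config.drop_btla:
        df = df.drop(index="BTLA")
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "tissue": "melanoma",
            "condition": "tumor",
            "arm": arms,
            "response": np.where(responder, "responder", "non-responder"),
            "pathology_score": pathology,
            "true_infiltration": infiltration,
        }
    )
    matrix = ExpressionMatrix(df)
    meta = validate_metadata(meta, matrix)
    truth = {
        "latent": pd.Series(latent, index=sample_ids),
        "loadings": pd.Series(loadings, index=genes),
        "responder": pd.Series(responder, index=sample_ids),
    }
    return SyntheticCohort(matrix=matrix, meta=meta, config=config, truth=truth)


def config_to_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    d["panel_loading_range"] = list(d["panel_loading_range"])
    return d


def config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    if "panel_loading_range" in d:
        d["panel_loading_range"] = tuple(d["panel_loading_range"])
    return CohortConfig(**d)


def with_seed(config: CohortConfig, seed: int) -> CohortConfig:
    return replace(config, seed=seed)
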