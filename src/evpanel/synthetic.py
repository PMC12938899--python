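"""Synthetic PEA cohorts with planted, recoverable structure.

Emulates a case/control EV-proteomics study measured on a targeted PEA panel:
healthy controls (HC), patients at baseline (PT_BE) and a subset of patients
at follow-up after treatment (PT_FU). Ground truth — which proteins carry a
diagnostic shift and which couple to treatment response — is returned
alongside the data so every downstream stage has a known answer.

Model
-----
Per-protein baseline NPX is independent normal: protein ``j`` has mean
``mu_j`` (drawn once per cohort) and standard deviation ``noise_sd``.
Planted diagnostic proteins add ``effect_log2`` to the patient-baseline mean.
Follow-up values are ``baseline - fu_reversion * effect + fresh noise``,
modelling partial reversion of the disease signal under treatment.
Missingness is MCAR at ``missing_rate``; the lower ``lod_quantile`` tail of
each protein's control distribution is flagged below-LOD (flagged, not
truncated — the filter stage owns censoring).

Treatment-response coupling uses a Gaussian copula on ranks: a latent
per-patient severity normal drives %dSLD through a monotone (log-normal)
transform, and planted response proteins' dNPX shares the latent with Pearson
correlation ``2*sin(pi*rho/6)``, which yields Spearman correlation ``rho``
exactly in population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .matrix import ExpressionMatrix, GROUP_HC, GROUP_BASELINE, GROUP_FOLLOWUP


@dataclass
class SyntheticConfig:
    """Cohort shape and planted-signal parameters.

    Defaults mirror the emulated study: 28 healthy controls, 29 patients of
    whom 27 have follow-up imaging, a 60-protein panel with two strongly
    discriminative proteins (+2 NPX, i.e. 4-fold, at noise SD 1), and three
    proteins whose within-patient change couples to %dSLD at Spearman 0.6.
    """

    n_hc: int = 28
    n_pt: int = 29
    n_fu: int = 27
    n_proteins: int = 60
    n_planted_diag: int = 2
    effect_log2: float = 2.0
    fu_reversion: float = 0.5
    missing_rate: float = 0.05
    lod_quantile: float = 0.05
    n_planted_resp: int = 3
    resp_rho: float = 0.6
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_hc", "n_pt", "n_fu", "n_proteins", "n_planted_diag", "n_planted_resp"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigurationError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_fu > self.n_pt:
            raise ConfigurationError(f"n_fu ({self.n_fu}) must not exceed n_pt ({self.n_pt})")
        if self.n_planted_diag + self.n_planted_resp > self.n_proteins:
            raise ConfigurationError(
                "n_planted_diag + n_planted_resp exceeds n_proteins "
                f"({self.n_planted_diag} + {self.n_planted_resp} > {self.n_proteins})"
            )
        for name, lo, hi in (
            ("fu_reversion", 0.0, 1.0),
            ("missing_rate", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ConfigurationError(f"{name} must be in [{lo}, {hi}], got {v!r}")
        if not 0.0 <= self.lod_quantile < 1.0:
            raise ConfigurationError(f"lod_quantile must be in [0, 1), got {self.lod_quantile!r}")
        if not abs(self.resp_rho) < 1.0:
            raise ConfigurationError(f"resp_rho must be in (-1, 1), got {self.resp_rho!r}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort."""

    planted_diag_ids: list[str]
    planted_resp_ids: list[str]
    true_effects: dict[str, float]
    true_resp_rho: dict[str, float]
    protein_ids: list[str] = field(default_factory=list)


@dataclass
class ResponseData:
    """Per-patient tumor-burden change and protein change (synthetic)."""

    subject_id: pd.Index
    sld_baseline: pd.Series  # mm
    sld_followup: pd.Series  # mm
    pct_delta_sld: pd.Series  # percent; negative = regression
    delta_npx: pd.DataFrame  # subjects x proteins, follow-up minus baseline


def _protein_names(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"P{i + 1:0{width}d}" for i in range(n)]


def spearman_to_pearson(rho: float) -> float:
    """Pearson latent correlation giving Spearman ``rho`` under a Gaussian copula."""
    return 2.0 * math.sin(math.pi * rho / 6.0)


def generate_npx_cohort(config: SyntheticConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate an NPX cohort with planted diagnostic structure.

    Returns the expression matrix (HC + PT_BE + PT_FU rows) and the ground
    truth. Fully reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    p = config.n_proteins
    proteins = _protein_names(p)

    n_planted = config.n_planted_diag + config.n_planted_resp
    planted_idx = rng.choice(p, size=n_planted, replace=False) if n_planted else np.array([], int)
    diag_idx = planted_idx[: config.n_planted_diag]
    resp_idx = planted_idx[config.n_planted_diag:]
    effect = np.zeros(p)
    effect[diag_idx] = config.effect_log2

    mu = rng.normal(4.0, 1.5, size=p)
    sd = config.noise_sd

    hc = mu + rng.normal(0.0, sd, size=(config.n_hc, p))
    be = mu + effect + rng.normal(0.0, sd, size=(config.n_pt, p))

    # follow-up rows belong to the first n_fu patient subjects; the latent
    # severity normal z0 couples planted response proteins' fresh noise so the
    # realized dNPX carries the configured Spearman correlation with %dSLD
    z0 = rng.normal(0.0, 1.0, size=config.n_fu)
    eps = rng.normal(0.0, 1.0, size=(config.n_fu, p))
    r = spearman_to_pearson(config.resp_rho)
    noise_fu = eps.copy()
    if len(resp_idx):
        noise_fu[:, resp_idx] = r * z0[:, None] + math.sqrt(1.0 - r * r) * eps[:, resp_idx]
    fu = be[: config.n_fu] - config.fu_reversion * effect + sd * noise_fu

    values = np.vstack([hc, be, fu])
    hc_ids = [f"HC{i + 1:03d}" for i in range(config.n_hc)]
    pt_subjects = [f"PT{i + 1:03d}" for i in range(config.n_pt)]
    sample_ids = (
        hc_ids
        + [f"{s}_BE" for s in pt_subjects]
        + [f"{s}_FU" for s in pt_subjects[: config.n_fu]]
    )
    groups = (
        [GROUP_HC] * config.n_hc
        + [GROUP_BASELINE] * config.n_pt
        + [GROUP_FOLLOWUP] * config.n_fu
    )
    subjects = hc_ids + pt_subjects + pt_subjects[: config.n_fu]

    df = pd.DataFrame(values, index=pd.Index(sample_ids, name="sample_id"), columns=proteins)

    # per-protein LOD from the control distribution
    if config.lod_quantile > 0 and config.n_hc > 0:
        lod = df.iloc[: config.n_hc].quantile(config.lod_quantile)
    else:
        lod = pd.Series(-np.inf, index=df.columns)
    below = df.lt(lod, axis=1)

    # MCAR missingness
    if config.missing_rate > 0:
        mask = rng.random(df.shape) < config.missing_rate
        df = df.mask(mask)
        below = below & ~mask

    matrix = ExpressionMatrix(
        values=df,
        sample_group=pd.Series(groups, index=df.index, name="group"),
        subject_id=pd.Series(subjects, index=df.index, name="subject_id"),
        below_lod=below,
        lod=lod,
    )
    truth = GroundTruth(
        planted_diag_ids=[proteins[i] for i in diag_idx],
        planted_resp_ids=[proteins[i] for i in resp_idx],
        true_effects={proteins[i]: config.effect_log2 for i in diag_idx},
        true_resp_rho={proteins[i]: config.resp_rho for i in resp_idx},
        protein_ids=proteins,
    )
    return matrix, truth


def generate_ct_data(
    n_samples: int, n_analytes: int, seed: int = 0, n_plates: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate Ct-level PEA readouts plus the NPX matrix they imply.

    The readout table is long-format with one row per (sample, analyte):
    analyte Ct, extension-control Ct, per-plate inter-plate-control dCt and
    per-analyte correction factor. The bundled NPX truth is computed from the
    same (rounded) Ct quantities via the three-step NPX formula, so the
    round trip through :func:`evpanel.npx.compute_npx` is exact.
    """
    if n_samples < 1 or n_analytes < 1:
        raise ConfigurationError("n_samples and n_analytes must be >= 1")
    rng = np.random.default_rng(seed)
    if n_plates is None:
        n_plates = 2 if n_samples >= 8 else 1
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    analytes = _protein_names(n_analytes)
    plate_of = {s: f"PL{(i % n_plates) + 1}" for i, s in enumerate(samples)}

    cf = np.round(rng.normal(10.0, 1.0, size=n_analytes), 3)
    ipc = np.round(rng.normal(3.0, 0.3, size=(n_plates, n_analytes)), 3)
    ext = np.round(rng.normal(20.0, 0.5, size=n_samples), 3)
    npx_target = rng.normal(4.0, 2.0, size=(n_samples, n_analytes))

    rows = []
    true = np.empty((n_samples, n_analytes))
    for i, s in enumerate(samples):
        plate = plate_of[s]
        pi = int(plate[2:]) - 1
        ct = np.round(ext[i] + ipc[pi] + cf - npx_target[i], 3)
        # NPX implied by the rounded Ct quantities (exact round-trip target)
        true[i] = cf - ((ct - ext[i]) - ipc[pi])
        for j, a in enumerate(analytes):
            rows.append(
                {
                    "sample_id": s,
                    "analyte_id": a,
                    "plate_id": plate,
                    "ct_analyte": ct[j],
                    "ct_extension_control": ext[i],
                    "dct_interplate_control": ipc[pi, j],
                    "correction_factor": cf[j],
                }
            )
    readouts = pd.DataFrame(rows)
    true_npx = pd.DataFrame(
        true, index=pd.Index(samples, name="sample_id"), columns=analytes
    )
    return readouts, true_npx


def generate_response_data(
    n_patients: int,
    planted: GroundTruth,
    resp_rho: float,
    seed: int = 0,
    noise_sd: float = 1.0,
) -> ResponseData:
    """Generate per-patient SLD values and dNPX vectors with copula coupling.

    Planted response proteins (``planted.planted_resp_ids``) achieve population
    Spearman correlation ``resp_rho`` between dNPX and %dSLD; all other
    proteins in ``planted.protein_ids`` are independent of %dSLD.
    """
    if n_patients < 5:
        raise ConfigurationError(f"n_patients must be >= 5, got {n_patients}")
    if not abs(resp_rho) < 1.0:
        raise ConfigurationError(f"resp_rho must be in (-1, 1), got {resp_rho!r}")
    proteins = list(planted.protein_ids) or list(planted.planted_resp_ids)
    missing = set(planted.planted_resp_ids) - set(proteins)
    if missing:
        raise ConfigurationError(f"planted response ids not in protein universe: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    subjects = pd.Index([f"PT{i + 1:03d}" for i in range(n_patients)], name="subject_id")

    z0 = rng.normal(size=n_patients)
    sld_be = np.exp(rng.normal(np.log(80.0), 0.35, size=n_patients))
    # monotone log-normal transform keeps follow-up SLD positive and preserves ranks
    sld_fu = sld_be * np.exp(-0.45 + 0.5 * z0)
    pct = 100.0 * (sld_fu - sld_be) / sld_be

    r = spearman_to_pearson(resp_rho)
    eps = rng.normal(size=(n_patients, len(proteins)))
    delta = math.sqrt(2.0) * noise_sd * eps  # dNPX of two noisy measurements
    resp_cols = [proteins.index(pid) for pid in planted.planted_resp_ids]
    for j, col in enumerate(resp_cols):
        delta[:, col] = math.sqrt(2.0) * noise_sd * (
            r * z0 + math.sqrt(1.0 - r * r) * eps[:, col]
        )
    return ResponseData(
        subject_id=subjects,
        sld_baseline=pd.Series(sld_be, index=subjects, name="sld_baseline"),
        sld_followup=pd.Series(sld_fu, index=subjects, name="sld_followup"),
        pct_delta_sld=pd.Series(pct, index=subjects, name="pct_delta_sld"),
        delta_npx=pd.DataFrame(delta, index=subjects, columns=proteins),
    )
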