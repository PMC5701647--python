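"""Synthetic cohorts of paired structural/functional connectomes.

Every downstream stage of the pipeline (hemispheric split, graph
metrics, laterality index, paired network-based statistic, group
statistics) is exercised against cohorts generated here, where the
hemispheric asymmetry is *known by construction*:

* structural connectomes are sparse symmetric 90x90 streamline-density
  matrices whose left intrahemispheric block is a mirrored copy of the
  right block (plus subject noise), optionally scaled by injected
  global / nodal / edge-level effects;
* functional inputs are ROI time series drawn from a block-modular
  multivariate normal whose covariance is mirrored across hemispheres;
* behavioral scores are linearly coupled to each subject's true
  generating asymmetry with a specified population correlation.

The generators emulate the statistical character of elderly-cohort
connectome data (sparse log-normal streamline densities, modular
positive functional correlations, the demographic ranges of a
community-dwelling sample aged 60-82) without modeling tractography or
hemodynamics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .regions import N_PAIRS, N_REGIONS, default_node_table, hemisphere_indices

logger = logging.getLogger(__name__)

#: Behavioral battery: column -> (population mean, population SD) for an
#: elderly community-dwelling sample.
BEHAVIOR_SCORES: dict[str, tuple[float, float]] = {
    "RAVLT_ir": (47.18, 10.76),
    "RAVLT_dr": (10.20, 3.04),
    "DigitSpan_fwd": (10.54, 2.65),
    "DigitSpan_bwd": (6.08, 2.21),
    "SDMT_written": (31.95, 11.56),
    "SDMT_oral": (39.17, 12.89),
    "BostonNaming": (22.13, 5.08),
    "BlockDesign": (26.93, 9.15),
    "CTT1": (69.34, 26.86),
    "CTT2": (136.10, 43.56),
    "MMSE": (28.25, 1.81),
    "MoCA": (25.75, 3.48),
}

DEFAULT_STRUCTURAL_PARAMS: dict[str, Any] = {
    # intrahemispheric edge density typical of deterministic tractography
    # on a 45-node parcellation
    "density_intra": 0.30,
    # interhemispheric (callosal) edges are sparser
    "density_inter": 0.10,
    # log-normal streamline-density weights (log-scale mean / sd)
    "weight_mu": -3.0,
    "weight_sigma": 1.0,
    # multiplicative log-normal subject noise (sd of log weight)
    "noise_sd": 0.10,
    # one template per cohort: edge support and base weights are shared
    "template_seed": 0,
}

DEFAULT_COV_SPEC: dict[str, Any] = {
    # 5 modules over the 45 homotopic pairs (mirrored across hemispheres)
    "module_sizes": [9, 9, 9, 9, 9],
    "rho_in": 0.40,
    "rho_out": 0.10,
    # homotopic / interhemispheric coupling
    "rho_inter": 0.10,
    "repair_pd": True,
}


@dataclass(frozen=True)
class AsymmetrySpec:
    """Ground-truth hemispheric effects injected into one hemisphere.

    Parameters
    ----------
    global_scale_delta
        All intrahemispheric weights of the target hemisphere are
        multiplied by ``1 + delta``.
    nodal_targets
        ``(pair_index, delta)`` entries: every edge incident to that
        region (within the target hemisphere) is additionally scaled.
    edge_subnetwork
        ``(pair_i, pair_j, delta)`` entries scaling individual
        intrahemispheric edges (1-based pair indices); the template is
        forced to contain these edges.
    direction
        ``"leftward"`` scales the left block (left metrics increase,
        AS < 0), ``"rightward"`` the right block.
    """

    global_scale_delta: float = 0.0
    nodal_targets: tuple[tuple[int, float], ...] = ()
    edge_subnetwork: tuple[tuple[int, int, float], ...] = ()
    direction: str = "leftward"

    def __post_init__(self) -> None:
        if 1.0 + self.global_scale_delta <= 0:
            raise ValueError("1 + global_scale_delta must be positive")
        if self.direction not in ("leftward", "rightward"):
            raise ValueError(f"unknown direction: {self.direction!r}")
        seen = set()
        for i, j, _ in self.edge_subnetwork:
            if i == j:
                raise ValueError("edge_subnetwork entries must join distinct regions")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"edge listed twice in edge_subnetwork: {key}")
            seen.add(key)

    def is_null(self) -> bool:
        return (
            self.global_scale_delta == 0.0
            and not self.nodal_targets
            and not self.edge_subnetwork
        )

    def effect_matrix(self, n: int = N_PAIRS) -> np.ndarray:
        """45x45 multiplicative effect applied to the target hemisphere block."""
        m = np.full((n, n), 1.0 + self.global_scale_delta)
        for pair_index, delta in self.nodal_targets:
            k = pair_index - 1
            m[k, :] *= 1.0 + delta
            m[:, k] *= 1.0 + delta
        for i, j, delta in self.edge_subnetwork:
            m[i - 1, j - 1] *= 1.0 + delta
            m[j - 1, i - 1] *= 1.0 + delta
        np.fill_diagonal(m, 1.0)
        return m

    def to_dict(self) -> dict[str, Any]:
        return {
            "global_scale_delta": self.global_scale_delta,
            "nodal_targets": [list(t) for t in self.nodal_targets],
            "edge_subnetwork": [list(t) for t in self.edge_subnetwork],
            "direction": self.direction,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AsymmetrySpec":
        return cls(
            global_scale_delta=float(d.get("global_scale_delta", 0.0)),
            nodal_targets=tuple(tuple(t) for t in d.get("nodal_targets", ())),
            edge_subnetwork=tuple(tuple(t) for t in d.get("edge_subnetwork", ())),
            direction=d.get("direction", "leftward"),
        )


@dataclass
class SubjectRecord:
    subject_id: str
    structural: np.ndarray  # 90x90 streamline-density matrix
    timeseries: np.ndarray  # n_timepoints x 90
    covariates: dict[str, Any]
    true_as: float  # generating laterality of total structural weight


@dataclass
class CohortBundle:
    subjects: list[SubjectRecord]
    behavior: pd.DataFrame
    node_table: pd.DataFrame
    truth: dict[str, Any] = field(default_factory=dict)

    @property
    def covariates(self) -> pd.DataFrame:
        return pd.DataFrame([{"subject_id": s.subject_id, **s.covariates} for s in self.subjects])


def _subject_seed(master_seed: int, index: int) -> int:
    """Deterministic per-subject seed, independent of iteration order."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31))


def _structural_template(
    node_table: pd.DataFrame, params: dict[str, Any], spec: AsymmetrySpec
) -> np.ndarray:
    """Cohort-level 90x90 base matrix with mirrored hemispheric blocks."""
    density_intra = params["density_intra"]
    density_inter = params["density_inter"]
    if not (0 < density_intra <= 1) or not (0 < density_inter <= 1):
        raise ValueError("edge densities must lie in (0, 1]")
    rng = np.random.default_rng(params["template_seed"])
    left_idx, right_idx = hemisphere_indices(node_table)
    n = N_PAIRS

    iu = np.triu_indices(n, k=1)
    support = rng.random(len(iu[0])) < density_intra
    weights = np.exp(rng.normal(params["weight_mu"], params["weight_sigma"], len(iu[0])))
    # edges targeted by the injected subnetwork must exist in the template
    forced = {(min(i, j) - 1, max(i, j) - 1) for i, j, _ in spec.edge_subnetwork}
    for k, (i, j) in enumerate(zip(*iu)):
        if (i, j) in forced:
            support[k] = True
    hemi_block = np.zeros((n, n))
    hemi_block[iu] = np.where(support, weights, 0.0)
    hemi_block += hemi_block.T

    inter_support = rng.random((n, n)) < density_inter
    inter_w = np.exp(rng.normal(params["weight_mu"], params["weight_sigma"], (n, n)))
    inter_block = np.where(inter_support, inter_w, 0.0)

    template = np.zeros((N_REGIONS, N_REGIONS))
    template[np.ix_(left_idx, left_idx)] = hemi_block
    template[np.ix_(right_idx, right_idx)] = hemi_block
    template[np.ix_(left_idx, right_idx)] = inter_block
    template[np.ix_(right_idx, left_idx)] = inter_block.T
    return template


def simulate_structural_connectome(
    node_table: pd.DataFrame | None = None,
    base_params: dict[str, Any] | None = None,
    spec: AsymmetrySpec | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Simulate one subject's 90x90 streamline-density connectome.

    Left and right intrahemispheric blocks come from a single mirrored
    template, so under a null ``spec`` with zero noise the left block
    equals the mirrored right block exactly.  Injected effects multiply
    the target hemisphere's block; subject noise is multiplicative
    log-normal, drawn independently per entry (hence per hemisphere).
    """
    node_table = default_node_table() if node_table is None else node_table
    params = {**DEFAULT_STRUCTURAL_PARAMS, **(base_params or {})}
    spec = AsymmetrySpec() if spec is None else spec

    template = _structural_template(node_table, params, spec)
    left_idx, right_idx = hemisphere_indices(node_table)

    mat = template.copy()
    target = left_idx if spec.direction == "leftward" else right_idx
    block = mat[np.ix_(target, target)]
    mat[np.ix_(target, target)] = block * spec.effect_matrix()

    noise_sd = params["noise_sd"]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = np.exp(rng.normal(0.0, noise_sd, mat.shape))
        noise = np.triu(noise, k=1)
        noise += noise.T
        mat = mat * np.where(noise > 0, noise, 1.0)
    np.fill_diagonal(mat, 0.0)
    return mat


def _repair_pd(cov: np.ndarray) -> np.ndarray:
    """Clip eigenvalues to make a symmetric matrix positive definite."""
    vals, vecs = np.linalg.eigh((cov + cov.T) / 2.0)
    clipped = np.clip(vals, 1e-8, None)
    return (vecs * clipped) @ vecs.T


def modular_covariance(
    node_table: pd.DataFrame | None = None,
    cov_spec: dict[str, Any] | None = None,
    spec: AsymmetrySpec | None = None,
) -> np.ndarray:
    """Block-modular 90x90 population covariance, mirrored across hemispheres."""
    node_table = default_node_table() if node_table is None else node_table
    cs = {**DEFAULT_COV_SPEC, **(cov_spec or {})}
    spec = AsymmetrySpec() if spec is None else spec
    sizes = list(cs["module_sizes"])
    if sum(sizes) != N_PAIRS:
        raise ValueError(f"module sizes must sum to {N_PAIRS}, got {sum(sizes)}")
    rho_in, rho_out, rho_inter = cs["rho_in"], cs["rho_out"], cs["rho_inter"]
    if not rho_in >= rho_out >= 0:
        raise ValueError("require rho_in >= rho_out >= 0")

    module_of = np.repeat(np.arange(len(sizes)), sizes)  # per pair_index-1
    same_module = module_of[:, None] == module_of[None, :]
    hemi_block = np.where(same_module, rho_in, rho_out)
    np.fill_diagonal(hemi_block, 1.0)

    left_idx, right_idx = hemisphere_indices(node_table)
    cov = np.full((N_REGIONS, N_REGIONS), rho_inter)
    cov[np.ix_(left_idx, left_idx)] = hemi_block
    cov[np.ix_(right_idx, right_idx)] = hemi_block

    target = left_idx if spec.direction == "leftward" else right_idx
    eff = spec.effect_matrix()
    block = cov[np.ix_(target, target)].copy()
    off = ~np.eye(N_PAIRS, dtype=bool)
    block[off] = np.clip(block[off] * eff[off], -0.999, 0.999)
    cov[np.ix_(target, target)] = block
    np.fill_diagonal(cov, 1.0)

    min_eig = np.linalg.eigvalsh(cov).min()
    if min_eig <= 1e-10:
        if not cs.get("repair_pd", True):
            raise ValueError(f"covariance not positive definite (min eigenvalue {min_eig:.3g})")
        logger.warning(
            "covariance not positive definite (min eigenvalue %.3g); applying nearest-PD repair",
            min_eig,
        )
        cov = _repair_pd(cov)
    return cov


def simulate_roi_timeseries(
    node_table: pd.DataFrame | None = None,
    cov_spec: dict[str, Any] | None = None,
    n_timepoints: int = 200,
    spec: AsymmetrySpec | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Draw ``n_timepoints x 90`` ROI time series from the modular model."""
    if n_timepoints < 50:
        raise ValueError("n_timepoints must be >= 50")
    cov = modular_covariance(node_table, cov_spec, spec)
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
    z = rng.standard_normal((n_timepoints, cov.shape[0]))
    return z @ chol.T


def generate_behavior(
    as_scores: Sequence[float],
    coupling_r: float = 0.0,
    score_params: dict[str, tuple[float, float]] | None = None,
    coupled_scores: Sequence[str] = ("RAVLT_ir",),
    seed: int = 0,
) -> pd.DataFrame:
    """Behavioral scores linearly coupled to per-subject asymmetry.

    Coupled columns are ``mean + sd * (r*z + sqrt(1-r^2)*eps)`` with
    ``z`` the standardized asymmetry score, so the population
    correlation with the asymmetry equals ``coupling_r`` exactly;
    uncoupled columns are pure noise.
    """
    as_scores = np.asarray(as_scores, dtype=float)
    n = len(as_scores)
    if abs(coupling_r) > 1:
        raise ValueError("|coupling_r| must be <= 1")
    if coupling_r != 0 and n < 3:
        raise ValueError("need at least 3 subjects for a defined correlation")
    params = dict(BEHAVIOR_SCORES if score_params is None else score_params)
    unknown = set(coupled_scores) - set(params)
    if unknown:
        raise ValueError(f"coupled scores not in score table: {sorted(unknown)}")

    sd_as = as_scores.std()
    z = (as_scores - as_scores.mean()) / sd_as if sd_as > 0 else np.zeros(n)
    rng = np.random.default_rng(seed)
    cols = {}
    for name, (mean, sd) in params.items():
        eps = rng.standard_normal(n)
        if name in coupled_scores:
            latent = coupling_r * z + np.sqrt(max(0.0, 1 - coupling_r**2)) * eps
        else:
            latent = eps
        cols[name] = mean + sd * latent
    return pd.DataFrame(cols)


def _simulate_covariates(n_subjects: int, cov_config: dict[str, Any], rng: np.random.Generator):
    cfg = {
        "age_mean": 70.08,
        "age_sd": 5.30,
        "age_range": (60, 82),
        "prop_female": 61 / 76,
        "education_mean": 6.00,
        "education_sd": 3.98,
        **(cov_config or {}),
    }
    lo, hi = cfg["age_range"]
    age = np.clip(rng.normal(cfg["age_mean"], cfg["age_sd"], n_subjects), lo, hi).round(1)
    gender = np.where(rng.random(n_subjects) < cfg["prop_female"], "F", "M")
    education = np.clip(
        rng.normal(cfg["education_mean"], cfg["education_sd"], n_subjects), 0, None
    ).round(0)
    return [
        {
            "age": float(age[i]),
            "gender": str(gender[i]),
            "education": float(education[i]),
            "handedness": "R",
        }
        for i in range(n_subjects)
    ]


def simulate_cohort(
    n_subjects: int,
    config: dict[str, Any] | None = None,
    seed: int = 0,
) -> CohortBundle:
    """Generate a complete cohort with a recorded ground-truth block.

    ``config`` may nest ``structural`` (streamline-density generator
    parameters), ``timeseries`` (``cov_spec`` plus ``n_timepoints``),
    ``asymmetry`` (an :class:`AsymmetrySpec` or its dict form),
    ``behavior`` (``coupling_r``, ``coupled_scores``) and
    ``covariates``.  Per-subject seeds are derived deterministically
    from the master seed, so the bundle is reproducible bit-for-bit.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    config = config or {}
    node_table = config.get("node_table")
    node_table = default_node_table() if node_table is None else node_table

    spec = config.get("asymmetry", AsymmetrySpec())
    if isinstance(spec, dict):
        spec = AsymmetrySpec.from_dict(spec)
    struct_params = {**DEFAULT_STRUCTURAL_PARAMS, **config.get("structural", {})}
    if struct_params.get("template_seed") is None:
        struct_params["template_seed"] = _subject_seed(seed, -1)
    ts_config = config.get("timeseries", {})
    cov_spec = {**DEFAULT_COV_SPEC, **ts_config.get("cov_spec", {})}
    n_timepoints = int(ts_config.get("n_timepoints", 200))
    behavior_cfg = config.get("behavior", {})

    left_idx, right_idx = hemisphere_indices(node_table)
    subjects = []
    for i in range(n_subjects):
        s_seed = _subject_seed(seed, i)
        structural = simulate_structural_connectome(node_table, struct_params, spec, s_seed)
        timeseries = simulate_roi_timeseries(
            node_table, cov_spec, n_timepoints, spec, _subject_seed(seed, i + n_subjects)
        )
        total_l = structural[np.ix_(left_idx, left_idx)].sum()
        total_r = structural[np.ix_(right_idx, right_idx)].sum()
        true_as = 100.0 * (total_r - total_l) / (total_r + total_l)
        subjects.append(
            SubjectRecord(
                subject_id=f"sub-{i + 1:03d}",
                structural=structural,
                timeseries=timeseries,
                covariates={},
                true_as=true_as,
            )
        )

    cov_rng = np.random.default_rng(_subject_seed(seed, 2 * n_subjects))
    for subj, cov in zip(subjects, _simulate_covariates(n_subjects, config.get("covariates", {}), cov_rng)):
        subj.covariates = cov

    coupling_r = float(behavior_cfg.get("coupling_r", 0.0))
    coupled_scores = tuple(behavior_cfg.get("coupled_scores", ("RAVLT_ir",)))
    behavior = generate_behavior(
        [s.true_as for s in subjects],
        coupling_r=coupling_r,
        coupled_scores=coupled_scores,
        seed=_subject_seed(seed, 2 * n_subjects + 1),
    )
    behavior.insert(0, "subject_id", [s.subject_id for s in subjects])

    truth = {
        "master_seed": int(seed),
        "asymmetry_spec": spec.to_dict(),
        "structural_params": {k: v for k, v in struct_params.items()},
        "cov_spec": {k: v for k, v in cov_spec.items()},
        "n_timepoints": n_timepoints,
        "behavior_coupling": {"coupling_r": coupling_r, "coupled_scores": list(coupled_scores)},
        "true_as": {s.subject_id: s.true_as for s in subjects},
        "note": "all generator choices are synthetic modeling decisions; "
        "no empirical cohort underlies these draws",
    }
    return CohortBundle(subjects=subjects, behavior=behavior, node_table=node_table, truth=truth)
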