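"""Pooled-screen per-cell reporter table generator with a planted state axis.

The generator emulates a multiplexed 12-clone reporter screen: every well
contains all clones; drug wells receive a perturbation whose effect on the
12 pathways is a shared latent *state axis* component (two anticorrelated
pathway clusters, scaled by a per-drug weight ``s_d``) plus a drug-specific
idiosyncratic vector ``e_d``.  Effects emerge over time through saturating
ramps and shift the location parameter of each clone's per-cell readout
distribution.  DMSO wells carry only well-level nuisance variation.

Per-cell readouts follow the two reporter families:

* kinase translocation reporters (KTR): cytoplasm/nucleus ratio, generated as
  a logistic transform of a unit-variance normal latent;
* transcription-response-element reporters (TRE): background-subtracted
  nuclear intensity, generated as a lognormal transform of the same kind of
  latent.

Both transforms are strictly increasing, so the planted location shifts are
exactly what a distribution-free two-sample statistic should detect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Reporter panel: (pathway name, readout mode).  KTR reporters read out the
#: cytoplasm/nucleus ratio; TRE reporters the background-subtracted nuclear
#: mean.  The AKT reporter is a translocation construct and uses the ratio.
REPORTERS: tuple[tuple[str, str], ...] = (
    ("ERK", "ratio"),
    ("p38", "ratio"),
    ("JNK", "ratio"),
    ("PKA", "ratio"),
    ("AKT", "ratio"),
    ("p53", "nuclear_intensity"),
    ("WNT", "nuclear_intensity"),
    ("NFkB", "nuclear_intensity"),
    ("HIF", "nuclear_intensity"),
    ("RAR", "nuclear_intensity"),
    ("YAP/TAZ", "nuclear_intensity"),
    ("Geminin", "nuclear_intensity"),
)

PATHWAYS = tuple(name for name, _ in REPORTERS)
READOUT_MODE = dict(REPORTERS)

#: Pathways activated in the growth-stress ("p38") state ...
STATE_POSITIVE = ("ERK", "p38", "JNK", "PKA", "AKT")
#: ... and in the division-stress ("p53") state.
STATE_NEGATIVE = ("p53", "WNT", "NFkB", "HIF", "RAR", "YAP/TAZ")

DMSO = "DMSO"

_BACKGROUND = 100.0
_RATIO_MAX = 4.0
_TRE_BASE = 400.0
_TRE_SCALE = 0.35
_CONTROL_AREA = 600.0  # median segmented cell area in control, px
_AREA_CV = 0.3


def default_state_axis(pathways: tuple[str, ...] = PATHWAYS) -> np.ndarray:
    """Unit vector over pathways with opposite signs for the two clusters.

    Geminin (a cell-cycle phase marker, not a signaling branch) gets weight 0.
    """
    u = np.zeros(len(pathways))
    for i, p in enumerate(pathways):
        if p in STATE_POSITIVE:
            u[i] = 1.0
        elif p in STATE_NEGATIVE:
            u[i] = -1.0
    return u / np.linalg.norm(u)


@dataclass(frozen=True)
class DrugSpec:
    """One perturbant: shared-state weight ``s`` and idiosyncratic vector ``e``."""

    name: str
    s: float
    e: np.ndarray
    group: str = "C"  # planted group label: A (s>0), B (s<0), C (idiosyncratic)


@dataclass
class ScreenDesign:
    """Full specification of a synthetic pooled screen.

    Parameters
    ----------
    drugs
        Perturbants with their latent-state weights and idiosyncratic vectors.
    pathways
        Reporter names; readout modes from :data:`READOUT_MODE` unless
        overridden via ``modes``.
    n_dmso_wells
        Number of vehicle-control wells (39 in the default layout).
    timepoints
        Imaging times in hours; must start at 0 (pre-treatment).
    cells_per_well
        Expected cells per clone per well per timepoint (Poisson); the default
        656 matches the sampling-depth regime of a 384-well screen.
    state_axis
        Unit vector over pathways; defaults to :func:`default_state_axis`.
    state_tau_h, idio_tau_h
        Time constants of the saturating ramps ``1 - exp(-t/tau)`` applied to
        the shared-state and idiosyncratic effect components.  The
        compound-specific shock acts faster than the shared stress response.
    well_jitter_sd
        SD of a scalar well-level nuisance shift applied to all clones.
    well_state_sd
        SD of a well-level coefficient along the state axis; models the
        pre-treatment well-to-well variation in growth/division balance that
        makes the state detectable before any drug is applied.
    """

    drugs: tuple[DrugSpec, ...]
    pathways: tuple[str, ...] = PATHWAYS
    modes: dict[str, str] = field(default_factory=lambda: dict(READOUT_MODE))
    n_dmso_wells: int = 39
    timepoints: tuple[float, ...] = (0.0, 12.0, 24.0, 36.0, 48.0)
    cells_per_well: float = 656.0
    state_axis: np.ndarray | None = None
    state_tau_h: float = 12.0
    idio_tau_h: float = 3.0
    well_jitter_sd: float = 0.05
    well_state_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cells_per_well <= 0:
            raise ValueError("cells_per_well must be > 0")
        if self.state_axis is None:
            self.state_axis = default_state_axis(self.pathways)
        u = np.asarray(self.state_axis, dtype=float)
        if not math.isclose(float(np.linalg.norm(u)), 1.0, rel_tol=1e-9):
            raise ValueError("state_axis must have unit norm")
        self.state_axis = u
        if min(self.timepoints) != 0.0:
            raise ValueError("timepoints must include 0 (pre-treatment)")
        for d in self.drugs:
            if len(d.e) != len(self.pathways):
                raise ValueError(f"drug {d.name}: e has wrong length")
        for p in self.pathways:
            if p not in self.modes:
                raise ValueError(f"no readout mode for pathway {p!r}")

    def ramp_state(self, t: np.ndarray | float) -> np.ndarray | float:
        return 1.0 - np.exp(-np.asarray(t, dtype=float) / self.state_tau_h)

    def ramp_idio(self, t: np.ndarray | float) -> np.ndarray | float:
        return 1.0 - np.exp(-np.asarray(t, dtype=float) / self.idio_tau_h)


@dataclass
class ScreenTruth:
    """Planted ground truth of a generated screen."""

    pathways: tuple[str, ...]
    timepoints: tuple[float, ...]
    state_axis: np.ndarray
    #: (n_drugs, n_timepoints, n_pathways) true effect vectors w_d(t)
    effects: np.ndarray
    #: per drug: group, s, relative growth/division rates, imbalance, mean area
    drug_table: pd.DataFrame
    #: well -> treatment map (includes DMSO wells)
    platemap: pd.DataFrame
    #: control (DMSO) division rate [1/h] and growth rate [1/h]
    control_alpha: float = math.log(2.0) / 24.0
    control_gamma: float = math.log(2.0) / 24.0


def three_group_design(
    n_drugs: int = 100,
    frac_conforming: float = 0.8,
    s_range: tuple[float, float] = (3.0, 6.0),
    e_sd_conforming: float = 0.35,
    e_sd_idiosyncratic: float = 1.2,
    seed: int = 0,
    **design_kwargs,
) -> ScreenDesign:
    """A screen design with three planted drug groups.

    Groups A and B load on the state axis with opposite signs (the two
    signaling states); group C drugs have no shared-state component, only an
    idiosyncratic response.  ``s_range`` is in units of the per-cell latent SD
    summed over the axis, i.e. ``s=4`` shifts each loaded pathway by about
    ``4/sqrt(11) = 1.2`` latent SDs at full ramp.
    """
    rng = np.random.default_rng(seed)
    n_conf = int(round(frac_conforming * n_drugs))
    n_a = n_conf // 2
    n_b = n_conf - n_a
    p = len(design_kwargs.get("pathways", PATHWAYS))
    drugs = []
    for i in range(n_drugs):
        if i < n_a:
            group, s = "A", float(rng.uniform(*s_range))
            e_sd = e_sd_conforming
        elif i < n_a + n_b:
            group, s = "B", -float(rng.uniform(*s_range))
            e_sd = e_sd_conforming
        else:
            group, s = "C", 0.0
            e_sd = e_sd_idiosyncratic
        e = rng.normal(0.0, e_sd, size=p)
        drugs.append(DrugSpec(f"drug_{i + 1:03d}", s, e, group))
    return ScreenDesign(drugs=tuple(drugs), seed=seed, **design_kwargs)


def _growth_truth(design: ScreenDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Per-drug growth/division ground truth coupled to the latent state.

    Growth-stress (s>0) drugs inhibit biosynthesis more than division
    (imbalance < 0, smaller cells); division-stress (s<0) drugs do the
    opposite.  Group C drugs perturb both rates equally and mildly.
    """
    s_max = max((abs(d.s) for d in design.drugs), default=1.0) or 1.0
    rows = []
    for d in design.drugs:
        strength = abs(d.s) / s_max
        if d.s > 0:  # growth-limited
            g_inh, a_inh = 0.6 * strength, 0.25 * strength
        elif d.s < 0:  # division-limited
            g_inh, a_inh = 0.25 * strength, 0.6 * strength
        else:
            g_inh = a_inh = 0.15 * float(np.linalg.norm(d.e)) / math.sqrt(len(d.e))
        gamma_rel = math.exp(-g_inh)
        alpha_rel = math.exp(-a_inh)
        imbalance = math.log2(gamma_rel / alpha_rel)
        mean_area = _CONTROL_AREA * (gamma_rel / alpha_rel)
        rows.append(
            {
                "drug": d.name,
                "group": d.group,
                "s": d.s,
                "gamma_rel": gamma_rel,
                "alpha_rel": alpha_rel,
                "imbalance": imbalance,
                "mean_area": mean_area,
            }
        )
    del rng  # reserved for future stochastic couplings
    return pd.DataFrame(rows).set_index("drug")


def generate_screen(design: ScreenDesign) -> tuple[pd.DataFrame, ScreenTruth]:
    """Generate the per-cell table and ground truth for a screen design.

    Returns
    -------
    cells
        One row per simulated cell: ``well``, ``drug``, ``time_h``, ``clone``
        (pathway name), compartment intensities (``cyto_mean``, ``nuc_mean``,
        ``bg_mean``) and segmented ``cell_area``.
    truth
        The planted effect vectors, growth truth, and platemap.
    """
    rng = np.random.default_rng(design.seed)
    u = design.state_axis
    pathways = design.pathways
    n_p = len(pathways)
    times = np.asarray(design.timepoints)
    n_t = len(times)

    drug_names = [d.name for d in design.drugs]
    n_drugs = len(drug_names)
    n_wells = n_drugs + design.n_dmso_wells
    well_names = [f"W{i + 1:03d}" for i in range(n_wells)]
    well_drug = drug_names + [DMSO] * design.n_dmso_wells

    # planted effects w_d(t) = ramp_s(t) * s_d * u + ramp_e(t) * e_d
    ramp_s = np.asarray(design.ramp_state(times))  # (T,)
    ramp_e = np.asarray(design.ramp_idio(times))
    s_vec = np.array([d.s for d in design.drugs])
    e_mat = np.array([d.e for d in design.drugs]) if n_drugs else np.zeros((0, n_p))
    effects = (
        ramp_s[None, :, None] * s_vec[:, None, None] * u[None, None, :]
        + ramp_e[None, :, None] * e_mat[:, None, :]
    )  # (D, T, P)

    # well-level nuisances
    jitter = rng.normal(0.0, design.well_jitter_sd, size=(n_wells, n_t))
    well_state = rng.normal(0.0, design.well_state_sd, size=n_wells)

    # per-(well, time, pathway) latent location
    mu = jitter[:, :, None] + well_state[:, None, None] * u[None, None, :]
    full = np.zeros((n_wells, n_t, n_p))
    full[:n_drugs] = effects
    mu = mu + full

    counts = rng.poisson(design.cells_per_well, size=(n_wells, n_t, n_p))
    total = int(counts.sum())
    flat_counts = counts.ravel()
    w_idx, t_idx, p_idx = np.unravel_index(np.arange(counts.size), counts.shape)
    w_rep = np.repeat(w_idx, flat_counts)
    t_rep = np.repeat(t_idx, flat_counts)
    p_rep = np.repeat(p_idx, flat_counts)

    z = np.repeat(mu.ravel(), flat_counts) + rng.standard_normal(total)

    # transform latents into compartment intensities per readout mode
    is_ratio = np.array([design.modes[p] == "ratio" for p in pathways])[p_rep]
    nuc = np.empty(total)
    cyto = np.empty(total)
    base_nuc = np.exp(rng.normal(math.log(500.0), 0.2, size=total))
    ratio = _RATIO_MAX / (1.0 + np.exp(-z))
    nuc[is_ratio] = base_nuc[is_ratio]
    cyto[is_ratio] = ratio[is_ratio] * base_nuc[is_ratio]
    tre = _TRE_BASE * np.exp(_TRE_SCALE * z)
    nuc[~is_ratio] = _BACKGROUND + tre[~is_ratio]
    cyto[~is_ratio] = 0.3 * nuc[~is_ratio]

    growth = _growth_truth(design, rng)
    area_mean = np.full(n_wells, _CONTROL_AREA)
    if n_drugs:
        area_mean[:n_drugs] = growth["mean_area"].to_numpy()
    sigma = math.sqrt(math.log1p(_AREA_CV**2))
    area = area_mean[w_rep] * np.exp(
        rng.normal(-0.5 * sigma**2, sigma, size=total)
    )

    well_cat = pd.Categorical.from_codes(w_rep, categories=well_names)
    drug_for_well = pd.Categorical(
        np.asarray(well_drug, dtype=object)[w_rep],
        categories=drug_names + [DMSO],
    )
    clone_cat = pd.Categorical.from_codes(p_rep, categories=list(pathways))
    cells = pd.DataFrame(
        {
            "well": well_cat,
            "drug": drug_for_well,
            "time_h": times[t_rep],
            "clone": clone_cat,
            "cyto_mean": cyto.astype(np.float32),
            "nuc_mean": nuc.astype(np.float32),
            "bg_mean": np.float32(_BACKGROUND),
            "cell_area": area.astype(np.float32),
        }
    )

    platemap = pd.DataFrame({"well": well_names, "treatment": well_drug})
    truth = ScreenTruth(
        pathways=pathways,
        timepoints=tuple(times),
        state_axis=u,
        effects=effects,
        drug_table=growth,
        platemap=platemap,
    )
    return cells, truth
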