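"""Synthetic images, dose panels, and Dmax matrices with known ground truth.

The generator emulates the measurement design of a high-content proximal
tubular cell screen: 24 PTC-toxic and 20 non-PTC-toxic compounds, seven doses
(1.6-1000 ug/mL), three biological replicates, and 129 phenotypic features of
which a small informative subset shifts under toxic compounds while non-toxic
compounds induce small or no change.  Per-compound phenotype responses follow
the same 4-parameter log-logistic model on molar concentration that the
dose-response stage fits, so planted maximal responses are analytically
known.  Cell images are rendered as elliptical nuclei inside elliptical
cells, with chromatin punctateness mapped to the number and contrast of
bright DNA foci drawn from a spatial Poisson process.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk, ellipse

from .catalog import default_catalog
from .doseresponse import REFERENCE_MOLAR, log_logistic, ug_per_ml_to_molar
from .imaging import MultiChannelCellImage, SegmentationMask

#: the tested dose grid, in ug/mL
DEFAULT_DOSE_GRID = (1.6, 16.0, 63.0, 125.0, 250.0, 500.0, 1000.0)


@dataclass(frozen=True)
class PhenotypeEffectModel:
    """Planted log-logistic response of one feature to one compound.

    ``b, c, d, e`` parameterize the response on molar concentration (c/d are
    the lower/upper limits, e the half-way concentration, b the relative
    slope); ``responder_fraction`` is the proportion of cells that respond
    (population-level panels see the mixture of responders and
    non-responders).  When ``d == c`` the induced response is identically 0.
    """

    feature_name: str
    b: float
    c: float
    d: float
    e: float
    responder_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.b, self.c, self.d, self.e]).all():
            raise ValueError("effect parameters must be finite")
        if self.e <= 0:
            raise ValueError("half-way concentration e must be positive")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must lie in [0, 1]")

    def delta(self, molar) -> np.ndarray:
        """Planted log2-response at the given molar concentration(s)."""
        return log_logistic(molar, self.b, self.c, self.d, self.e)

    def delta_max(self, reference: float = REFERENCE_MOLAR) -> float:
        """Analytic maximal response: the curve evaluated at 5 mM."""
        return float(self.delta(reference))

    def population_multiplier(self, molar) -> np.ndarray:
        """Fold change of the population mean given responder heterogeneity.

        Responders realize the full ``2**delta`` fold change, non-responders
        none; at responder_fraction = 1 this is exactly ``2**delta``.
        """
        f = self.responder_fraction
        return (1.0 - f) + f * 2.0 ** self.delta(molar)


@dataclass
class SyntheticPanelSpec:
    """Study-design parameters of a generated screen."""

    n_toxic: int = 24
    n_nontoxic: int = 20
    n_features: int = 129
    n_informative: int = 4
    effect_size: float = 2.0  # mean |Dmax| (log2 units) of informative features
    replicate_noise_sd: float = 0.3  # sd of log2 multiplicative replicate noise
    dose_grid: tuple[float, ...] = DEFAULT_DOSE_GRID
    n_replicates: int = 3
    seed: int = 0
    molecular_mass: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        grid = np.asarray(self.dose_grid, dtype=np.float64)
        if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
            raise ValueError("dose_grid must be strictly increasing and positive")
        if any(m <= 0 for m in self.molecular_mass.values()):
            raise ValueError("molecular masses must be positive")

    @property
    def compound_names(self) -> list[str]:
        return ([f"TOX{i + 1:02d}" for i in range(self.n_toxic)]
                + [f"NTX{i + 1:02d}" for i in range(self.n_nontoxic)])

    @property
    def labels(self) -> pd.Series:
        values = ["PTC-toxic"] * self.n_toxic + ["non-PTC-toxic"] * self.n_nontoxic
        return pd.Series(values, index=self.compound_names, name="label")

    @property
    def feature_names(self) -> list[str]:
        names = list(default_catalog()["name"])
        if self.n_features <= len(names):
            return names[: self.n_features]
        return names + [f"extra_{i}" for i in range(self.n_features - len(names))]

    def compounds_table(self, rng: np.random.Generator | None = None) -> pd.DataFrame:
        """Compound metadata: class label, molecular mass, solvent."""
        rng = rng or np.random.default_rng(self.seed)
        names = self.compound_names
        masses = dict(self.molecular_mass)
        for name in names:
            if name not in masses:
                masses[name] = float(rng.uniform(150.0, 600.0))
        solvents = [("DMSO" if i % 2 == 0 else "water") for i in range(len(names))]
        return pd.DataFrame({"label": self.labels.to_numpy(),
                             "molecular_mass": [masses[n] for n in names],
                             "solvent": solvents}, index=pd.Index(names, name="compound"))


# ---------------------------------------------------------------------------
# image synthesis
# ---------------------------------------------------------------------------

def generate_cell_image(n_cells: int, chromatin_punctateness: float = 0.0,
                        marker_levels: dict[str, float] | None = None,
                        seed: int = 0, cell_radius: int = 22,
                        ) -> tuple[MultiChannelCellImage, SegmentationMask]:
    """Render non-overlapping synthetic cells on a dark background.

    Cells sit on a regular grid so they never overlap.  The DNA channel of
    each nucleus carries ``chromatin_punctateness``-controlled bright foci on
    a correspondingly dimmer diffuse background, reproducing the punctate,
    high-CV / high-texture-entropy chromatin phenotype of DNA-damage
    responses.  Deterministic for a fixed seed.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not np.isfinite(chromatin_punctateness) or not 0.0 <= chromatin_punctateness <= 1.0:
        raise ValueError("chromatin_punctateness must be a finite value in [0, 1]")
    levels = {"dna": 20000.0, "secondary": 8000.0, "actin": 12000.0, "wcs": 10000.0}
    if marker_levels:
        for k, v in marker_levels.items():
            if k not in levels:
                raise ValueError(f"unknown marker channel {k!r}")
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"marker_levels[{k!r}] must be finite and nonnegative")
            levels[k] = float(v)

    rng = np.random.default_rng(seed)
    pitch = 2 * cell_radius + 8
    n_cols = int(np.ceil(np.sqrt(n_cells)))
    n_rows = int(np.ceil(n_cells / n_cols))
    shape = (n_rows * pitch, n_cols * pitch)

    channels = {k: np.zeros(shape, dtype=np.float64) for k in levels}
    nuclei = np.zeros(shape, dtype=np.int32)
    cells = np.zeros(shape, dtype=np.int32)

    nuc_radius = cell_radius // 2
    for idx in range(n_cells):
        label = idx + 1
        r0 = (idx // n_cols) * pitch + pitch // 2
        c0 = (idx % n_cols) * pitch + pitch // 2
        # slightly anisotropic cell and nucleus
        ang = rng.uniform(0, np.pi)
        rr, cc = ellipse(r0, c0, cell_radius, int(cell_radius * 0.8),
                         shape=shape, rotation=ang)
        cells[rr, cc] = label
        channels["wcs"][rr, cc] = levels["wcs"]
        channels["actin"][rr, cc] = levels["actin"] * rng.uniform(0.5, 1.5, size=rr.size)

        nr, nc = ellipse(r0, c0, nuc_radius, int(nuc_radius * 0.85),
                         shape=shape, rotation=ang)
        nuclei[nr, nc] = label
        # diffuse chromatin dims and grows speckled as punctateness rises;
        # heterogeneous bright foci carry the signal
        # the dial acts superlinearly so mid-dial settings land mid-way in
        # the texture statistics rather than saturating them
        dial = chromatin_punctateness ** 2
        diffuse = levels["dna"] * (1.0 - 0.45 * dial)
        speckle = dial * levels["dna"] * rng.normal(0.0, 0.3, size=nr.size)
        channels["dna"][nr, nc] = np.clip(diffuse + speckle, 0.0, None)
        channels["secondary"][nr, nc] = levels["secondary"]

        n_foci = rng.poisson(2 + 18 * dial)
        for _ in range(n_foci):
            fr = r0 + rng.integers(-nuc_radius + 2, nuc_radius - 1)
            fc = c0 + rng.integers(-nuc_radius + 2, nuc_radius - 1)
            if nuclei[fr, fc] != label:
                continue
            frr, fcc = disk((fr, fc), rng.uniform(1.0, 2.5), shape=shape)
            keep = nuclei[frr, fcc] == label
            # spread amplitudes below the 16-bit ceiling so foci levels stay
            # distinct, with per-pixel graininess inside each focus
            amp = levels["dna"] * (1.0 + 2.0 * dial * rng.uniform(0.4, 1.0))
            grain = 1.0 + 0.25 * dial * rng.normal(0.0, 1.0, size=int(keep.sum()))
            channels["dna"][frr[keep], fcc[keep]] = amp * np.clip(grain, 0.1, None)

    for k in channels:
        noise = rng.normal(0.0, 0.03 * levels[k] + 1.0, size=shape)
        channels[k] = np.clip(channels[k] + noise, 0, 65535).round()

    image = MultiChannelCellImage(channels={k: v.astype(np.uint16)
                                            for k, v in channels.items()})
    return image, SegmentationMask(nuclei=nuclei, cells=cells)


# ---------------------------------------------------------------------------
# dose panels and Dmax matrices
# ---------------------------------------------------------------------------

def default_effects(spec: SyntheticPanelSpec,
                    rng: np.random.Generator | None = None,
                    ) -> dict[tuple[str, str], PhenotypeEffectModel]:
    """Class-conditional effect models for the informative features.

    Toxic compounds get a saturating log-logistic response whose maximal
    response alternates in sign across informative features with mean
    magnitude ``effect_size``; non-toxic compounds get a null (d = c = 0)
    response, i.e. small or no change.
    """
    rng = rng or np.random.default_rng(spec.seed)
    informative = spec.feature_names[: spec.n_informative]
    masses = spec.compounds_table(rng=np.random.default_rng(spec.seed))["molecular_mass"]
    effects: dict[tuple[str, str], PhenotypeEffectModel] = {}
    for compound in spec.compound_names:
        toxic = compound.startswith("TOX")
        top_molar = ug_per_ml_to_molar(spec.dose_grid[-1], masses[compound])
        for k, feature in enumerate(informative):
            if toxic:
                sign = 1.0 if k % 2 == 0 else -1.0
                d = sign * spec.effect_size * rng.uniform(0.8, 1.2)
                e = float(top_molar * rng.uniform(0.05, 0.3))  # saturates in range
                effects[(compound, feature)] = PhenotypeEffectModel(
                    feature_name=feature, b=-2.0, c=0.0, d=float(d), e=e)
            else:
                effects[(compound, feature)] = PhenotypeEffectModel(
                    feature_name=feature, b=-1.0, c=0.0, d=0.0, e=1e-4)
    return effects


def generate_dose_panel(spec: SyntheticPanelSpec,
                        effects: dict[tuple[str, str], PhenotypeEffectModel] | None = None,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw per-condition feature table over (compound, dose, replicate).

    Feature value = control_level * population_multiplier(molar dose) * noise
    with multiplicative log-normal replicate noise; at responder_fraction = 1
    the multiplier is exactly ``2**Delta(molar)``.  Vehicle-control rows (one
    per solvent and replicate) are appended with ``vehicle_flag=True``.
    Returns ``(panel, compounds_metadata)``.
    """
    rng = np.random.default_rng(spec.seed)
    compounds = spec.compounds_table(rng=np.random.default_rng(spec.seed))
    effects = default_effects(spec) if effects is None else effects
    informative = {f for (_, f) in effects}
    for compound in spec.compound_names:
        for feature in informative:
            if (compound, feature) not in effects:
                raise ValueError(
                    f"missing effect model for {compound!r} x {feature!r}")

    features = spec.feature_names
    control_levels = rng.lognormal(mean=np.log(500.0), sigma=0.5, size=len(features))
    log2_sd = spec.replicate_noise_sd

    def noise(size):
        return 2.0 ** rng.normal(0.0, log2_sd, size=size)

    rows = []
    for compound in spec.compound_names:
        mass = compounds.loc[compound, "molecular_mass"]
        if mass is None or mass <= 0:
            raise ValueError(f"missing molecular mass for {compound!r}")
        molar = ug_per_ml_to_molar(np.asarray(spec.dose_grid), mass)
        for rep in range(1, spec.n_replicates + 1):
            for dose, x in zip(spec.dose_grid, molar):
                values = control_levels * noise(len(features))
                for k, feature in enumerate(features):
                    model = effects.get((compound, feature))
                    if model is not None:
                        values[k] *= float(model.population_multiplier(x))
                rows.append({"compound": compound, "dose_ug_per_ml": dose,
                             "replicate": rep, "vehicle_flag": False,
                             **dict(zip(features, values))})
    for solvent in sorted(compounds["solvent"].unique()):
        for rep in range(1, spec.n_replicates + 1):
            values = control_levels * noise(len(features))
            rows.append({"compound": solvent, "dose_ug_per_ml": 0.0,
                         "replicate": rep, "vehicle_flag": True,
                         **dict(zip(features, values))})
    return pd.DataFrame(rows), compounds


def generate_dmax_matrix(spec: SyntheticPanelSpec, effect_structure: str = "complementary",
                         ) -> tuple[pd.DataFrame, pd.Series]:
    """Directly sampled Dmax matrix (features x compounds) plus class labels.

    Informative features carry a class-dependent mean shift of magnitude
    ``effect_size`` (alternating sign across features) under toxic compounds
    and ~0 under non-toxic ones; every other entry is pure replicate-level
    noise.  With the default ``effect_structure='complementary'`` half of the
    toxic compounds respond in every informative feature while the rest are
    partitioned round-robin so that each informative feature uniquely covers
    one subgroup — every feature is then individually informative yet none is
    redundant, mirroring screens in which different toxicants induce
    different injury phenotypes and multi-feature classifiers beat the best
    single feature.  ``'shared'`` shifts every informative feature for every
    toxic compound (fully redundant signal).
    """
    if effect_structure not in ("complementary", "shared"):
        raise ValueError("effect_structure must be 'complementary' or 'shared'")
    rng = np.random.default_rng(spec.seed)
    features = spec.feature_names
    names = spec.compound_names
    labels = spec.labels
    values = rng.normal(0.0, spec.replicate_noise_sd, size=(len(features), len(names)))
    toxic_idx = np.where(labels.to_numpy() == "PTC-toxic")[0]
    n_core = len(toxic_idx) // 2  # compounds responding in every informative feature
    core, unique = toxic_idx[:n_core], toxic_idx[n_core:]
    for k in range(spec.n_informative):
        sign = 1.0 if k % 2 == 0 else -1.0
        if effect_structure == "shared":
            targets = toxic_idx
        else:
            own = unique[np.arange(len(unique)) % max(spec.n_informative, 1) == k]
            targets = np.concatenate([core, own])
        shift = sign * spec.effect_size * rng.uniform(0.8, 1.2, size=len(targets))
        values[k, targets] += shift
    matrix = pd.DataFrame(values, index=pd.Index(features, name="feature"),
                          columns=pd.Index(names, name="compound"))
    return matrix, labels
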