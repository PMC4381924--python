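"""Named study presets: receptor constructs and kinetics parameter sets.

Vesicle presets describe the dimerization behavior of each fluorescent-
protein-tagged construct (TM-only, ECD-TM with/without ligand, ΔL1, the
disulfide-locked H905C variant, and a monomeric control); live-cell presets
give the per-pixel efficiency distributions seen in the two-photon assay;
kinetics presets carry the published apparent parameters and substrate
grids used to generate synthetic velocity data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import SceneParams


@dataclass(frozen=True)
class VesiclePreset:
    """Dimerization ground truth for one construct in vesicles."""

    name: str
    Kd2d: float  # molecules/µm²
    E_dimer: float  # pairwise dimer FRET efficiency Ẽ
    x_a_true: float  # acceptor labeling fraction
    density_range: tuple[float, float]  # receptors/µm²
    expected_model: str  # "association" or "horizontal"

    def scene_params(self, total_density: float, seed: int) -> SceneParams:
        return SceneParams(total_density=total_density,
                           x_a_true=self.x_a_true, Kd2d=self.Kd2d,
                           E_dimer=self.E_dimer, seed=seed)


# Constitutive (always-dimer) constructs use a Kd far below their density
# range so the association curve is flat at the plateau — a horizontal
# line. 1e-3 µm⁻² keeps the dimer fraction above 0.999 everywhere.
_CONSTITUTIVE_KD = 1e-3

VESICLE_PRESETS: dict[str, VesiclePreset] = {
    # isolated transmembrane helix: concentration-driven monomer–dimer
    "tm_only": VesiclePreset("tm_only", Kd2d=150.0, E_dimer=0.38,
                             x_a_true=0.5, density_range=(100.0, 2000.0),
                             expected_model="association"),
    # full ECD holds the helices apart: constitutive dimer, low FRET
    "ecd_tm_unliganded": VesiclePreset("ecd_tm_unliganded",
                                       Kd2d=_CONSTITUTIVE_KD, E_dimer=0.21,
                                       x_a_true=0.5,
                                       density_range=(100.0, 1000.0),
                                       expected_model="horizontal"),
    # ligand releases the brake: helices approach, FRET rises
    "ecd_tm_liganded": VesiclePreset("ecd_tm_liganded",
                                     Kd2d=_CONSTITUTIVE_KD, E_dimer=0.34,
                                     x_a_true=0.5,
                                     density_range=(100.0, 1000.0),
                                     expected_model="horizontal"),
    # L1 deletion removes the separating contact
    "ecd_dl1": VesiclePreset("ecd_dl1", Kd2d=_CONSTITUTIVE_KD, E_dimer=0.36,
                             x_a_true=0.5, density_range=(100.0, 1000.0),
                             expected_model="horizontal"),
    # juxtamembrane disulfide lock
    "h905c": VesiclePreset("h905c", Kd2d=_CONSTITUTIVE_KD, E_dimer=0.38,
                           x_a_true=0.5, density_range=(100.0, 1000.0),
                           expected_model="horizontal"),
    # monomeric receptor control: proximity FRET only
    "monomer_control": VesiclePreset("monomer_control", Kd2d=1e9,
                                     E_dimer=0.38, x_a_true=0.5,
                                     density_range=(100.0, 1000.0),
                                     expected_model="horizontal"),
}


@dataclass(frozen=True)
class LiveCellPreset:
    """Per-pixel apparent-efficiency distribution in the live-cell assay."""

    name: str
    peaks: tuple[float, ...]
    widths: tuple[float, ...]
    weights: tuple[float, ...]

    @property
    def n_components(self) -> int:
        return len(self.peaks)


LIVE_CELL_PRESETS: dict[str, LiveCellPreset] = {
    "ecd_tm_liganded": LiveCellPreset("ecd_tm_liganded", peaks=(0.34,),
                                      widths=(0.09,), weights=(1.0,)),
    "ecd_tm_unliganded": LiveCellPreset("ecd_tm_unliganded", peaks=(0.21,),
                                        widths=(0.13,), weights=(1.0,)),
    "tm_only": LiveCellPreset("tm_only", peaks=(0.37, 0.33),
                              widths=(0.03, 0.11), weights=(0.5, 0.5)),
}


@dataclass(frozen=True)
class KineticsPreset:
    """Published apparent kinetic parameters and assay substrate grids.

    ``Km_app`` and ``kcat`` are the reported fitted values for the enzyme
    form; ``atp_grid_uM`` is the ATP series used in the assay. These are
    inputs to the synthetic velocity generator, not outputs.
    """

    name: str
    Km_app_uM: float
    kcat_per_min: float
    atp_grid_uM: tuple[float, ...]
    reported_specificity: float  # kcat/Km(ATP), µM⁻¹min⁻¹, 2 sig figs


KINETICS_PRESETS: dict[str, KineticsPreset] = {
    # phosphorylated full-length receptor with ligand bound
    "igf1r_fl_igf1_phos": KineticsPreset(
        "igf1r_fl_igf1_phos", Km_app_uM=82.0, kcat_per_min=459.0,
        atp_grid_uM=(500.0, 400.0, 300.0, 250.0, 125.0, 62.5, 31.3, 15.6,
                     7.8),
        reported_specificity=5.6),
    # phosphorylated full-length receptor without ligand
    "igf1r_fl_phos": KineticsPreset(
        "igf1r_fl_phos", Km_app_uM=89.0, kcat_per_min=749.0,
        atp_grid_uM=(500.0, 400.0, 300.0, 250.0, 125.0, 62.5, 31.3, 15.6,
                     7.8),
        reported_specificity=8.5),
    # phosphorylated intracellular domain
    "igf1r_icd_phos": KineticsPreset(
        "igf1r_icd_phos", Km_app_uM=79.0, kcat_per_min=385.0,
        atp_grid_uM=(500.0, 250.0, 125.0, 62.5, 31.3, 15.6, 7.8, 3.9),
        reported_specificity=4.9),
    # phosphorylated juxtamembrane+kinase fragment
    "igf1r_jmk_phos": KineticsPreset(
        "igf1r_jmk_phos", Km_app_uM=68.0, kcat_per_min=363.0,
        atp_grid_uM=(500.0, 250.0, 125.0, 62.5, 31.3, 15.6),
        reported_specificity=6.9),
    # phosphorylated isolated kinase domain
    "igf1r_kin_phos": KineticsPreset(
        "igf1r_kin_phos", Km_app_uM=115.0, kcat_per_min=98.0,
        atp_grid_uM=(1000.0, 500.0, 250.0, 125.0, 62.5, 31.3),
        reported_specificity=0.85),
}


def vesicle_density_series(preset: VesiclePreset, n_vesicles: int,
                           seed: int) -> np.ndarray:
    """Per-vesicle expression levels spanning the preset's density range.

    Log-uniform draws emulate the wide cell-to-cell expression spread seen
    in transient transfection.
    """
    rng = np.random.default_rng(seed)
    lo, hi = preset.density_range
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_vesicles))
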