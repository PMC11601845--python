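import numpy as np
import pandas as pd
import pytest

from codexspatial import TissueSimConfig, simulate_tissue

MARKER_TO_TYPE = {"PanCK": "Tumor", "CD8": "CD8T", "CD4": "CD4T",
                  "CD20": "B", "CD11c": "DC", "CD68": "Macrophage"}


def canonical_marker_means(types, contrast=30.0, background=1.0):
    """One defining marker per type at `contrast`-fold over background."""
    own = {t: m for m, t in MARKER_TO_TYPE.items() if t in types}
    markers = [own[t] for t in types]
    return {t: {m: (contrast if own[t] == m else background) for m in markers}
            for t in types}


def three_type_config(seed, cells=2000, noise_sd=0.4):
    """One well-mixed ROI with three marker-separable cell types."""
    types = ("Tumor", "CD8T", "B")
    return TissueSimConfig(
        n_rois=1, cells_per_roi=cells, cell_types=types,
        neighborhood_profiles={"mix": {"Tumor": 1 / 3, "CD8T": 1 / 3, "B": 1 / 3}},
        marker_means=canonical_marker_means(types), noise_sd=noise_sd, seed=seed)


def planted_cn_config(seed, n_rois=2, cells_per_roi=2500):
    """Three realistic (full-support) neighbourhood motifs: tumour-dominated,
    B-T lymphoid aggregate, DC-macrophage myeloid zone."""
    types = ("Tumor", "CD8T", "CD4T", "B", "DC", "Macrophage")
    profiles = {
        "TumorCore": {"Tumor": 0.75, "Macrophage": 0.10, "CD4T": 0.06,
                      "CD8T": 0.04, "DC": 0.03, "B": 0.02},
        "LymphoidAggregate": {"B": 0.35, "CD8T": 0.30, "CD4T": 0.20,
                              "DC": 0.08, "Macrophage": 0.04, "Tumor": 0.03},
        "MyeloidZone": {"DC": 0.45, "Macrophage": 0.35, "Tumor": 0.08,
                        "CD4T": 0.07, "CD8T": 0.03, "B": 0.02},
    }
    return TissueSimConfig(
        n_rois=n_rois, cells_per_roi=cells_per_roi, cell_types=types,
        neighborhood_profiles=profiles, neighborhood_radius=220.0,
        roi_extent=1500.0, regions_per_roi=5,
        marker_means=canonical_marker_means(types), noise_sd=0.4,
        cohort_effect={"all": {k: 1.0 for k in profiles}}, seed=seed)


@pytest.fixture(scope="session")
def small_tissue():
    """A small deterministic cohort shared by read-only tests."""
    cells, markers, truth = simulate_tissue(three_type_config(seed=11, cells=400))
    return cells, markers, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
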