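"""Registry of white-matter skeleton measures used throughout the pipeline.

The analysis operates on 25 ROI-level measures derived from a TBSS white-matter
skeleton labelled with the JHU atlas: 21 atomic tract ROIs (bilaterally
combined), 3 compound ROIs that are unions of atomic segments (full corpus
callosum, full corona radiata, full internal capsule), and the whole-skeleton
average ("AverageFA").  Voxel counts refer to the skeleton template; the
compound counts are exact sums of their parts, and the whole-skeleton count
includes the non-JHU "periphery" voxels that surround the labelled core.

``REFERENCE_D`` holds the published case-control Cohen's d for FA per measure
(patients minus controls, negative = lower FA in patients).  The simulator
uses these as its default ground-truth effect sizes so that recovery runs are
exercised at realistic magnitudes.
"""

from __future__ import annotations

PERIPHERY = "PERIPHERY"

#: atomic tract ROIs -> (skeleton voxel count, midline flag).
#: Midline structures (callosal segments, fornix body) are not split into
#: hemispheres; all others are stored per-hemisphere and bilaterally combined.
ATOMIC_ROIS: dict[str, tuple[int, bool]] = {
    "ACR": (3129, False),
    "ALIC": (1510, False),
    "BCC": (3173, True),
    "CGC": (594, False),
    "CGH": (524, False),
    "CST": (167, False),
    "EC": (2896, False),
    "FX": (222, True),
    "FXST": (706, False),
    "GCC": (1834, True),
    "IFO": (88, False),
    "PCR": (1437, False),
    "PLIC": (1775, False),
    "PTR": (1987, False),
    "RLIC": (1496, False),
    "SCC": (2311, True),
    "SCR": (2778, False),
    "SFO": (193, False),
    "SLF": (3503, False),
    "SS": (1294, False),
    "UNC": (125, False),
}

#: compound ROIs -> constituent atomic ROIs (voxel-count-weighted unions)
COMPOUND_ROIS: dict[str, tuple[str, ...]] = {
    "CC": ("GCC", "BCC", "SCC"),
    "CR": ("ACR", "SCR", "PCR"),
    "IC": ("ALIC", "PLIC", "RLIC"),
}

AVERAGE_FA = "AverageFA"

#: whole-skeleton voxel count (core + periphery)
N_SKELETON_VOXELS = 112_889

#: the ordered 25-measure registry: compounds and atomics sorted into the
#: published presentation order (descending |d|), AverageFA first.
ROI_REGISTRY: tuple[str, ...] = (
    AVERAGE_FA,
    "ACR", "CC", "BCC", "GCC", "ALIC", "CR", "FXST", "FX", "PTR", "SS",
    "SFO", "CGC", "PCR", "SCC", "SLF", "EC", "IC", "UNC", "SCR", "RLIC",
    "IFO", "CGH", "CST", "PLIC",
)

#: published FA case-control Cohen's d per measure (patients minus controls)
REFERENCE_D: dict[str, float] = {
    AVERAGE_FA: -0.42,
    "ACR": -0.40, "CC": -0.40, "BCC": -0.39, "GCC": -0.37, "ALIC": -0.37,
    "CR": -0.33, "FXST": -0.32, "FX": -0.31, "PTR": -0.31, "SS": -0.30,
    "SFO": -0.29, "CGC": -0.27, "PCR": -0.25, "SCC": -0.22, "SLF": -0.22,
    "EC": -0.21, "IC": -0.18, "UNC": -0.16, "SCR": -0.15, "RLIC": -0.13,
    "IFO": -0.11, "CGH": -0.11, "CST": -0.04, "PLIC": 0.04,
}

#: skeleton voxel count per registry measure
VOXEL_COUNTS: dict[str, int] = {
    **{roi: n for roi, (n, _) in ATOMIC_ROIS.items()},
    **{
        comp: sum(ATOMIC_ROIS[a][0] for a in parts)
        for comp, parts in COMPOUND_ROIS.items()
    },
    AVERAGE_FA: N_SKELETON_VOXELS,
}

#: study-level bookkeeping for the consortium sample the pipeline emulates
STUDY_SAMPLE = {"n_controls": 2359, "n_patients": 1963, "n_sites": 29}

N_CORE_VOXELS = sum(n for n, _ in ATOMIC_ROIS.values())
N_PERIPHERY_VOXELS = N_SKELETON_VOXELS - N_CORE_VOXELS

METRICS = ("FA", "MD", "AD", "RD")

MODERATORS = (
    "age_at_onset", "duration_years", "duration_pct", "cpz",
    "panss_total", "panss_pos", "panss_neg", "sans_total", "saps_total",
)


def check_registry() -> None:
    """Internal consistency checks; raises AssertionError on corruption."""
    assert len(ROI_REGISTRY) == 25
    assert set(ROI_REGISTRY) == set(REFERENCE_D) == set(VOXEL_COUNTS)
    for comp, parts in COMPOUND_ROIS.items():
        assert VOXEL_COUNTS[comp] == sum(VOXEL_COUNTS[p] for p in parts)
    assert N_PERIPHERY_VOXELS > 0
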