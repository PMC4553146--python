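"""Region label sets for the regional morphometry matrices.

Cortical parcellation follows the standard 34-region-per-hemisphere
Desikan-Killiany naming (68 cortical labels).  The volumetric set appends
the seven bilateral subcortical structures (amygdala, caudate, hippocampus,
pallidum, accumbens, putamen, thalamus) and bilateral cerebellar gray
matter, giving 84 labels.  Label ordering (all left-hemisphere labels, then
all right-hemisphere) is a package convention.
"""

from __future__ import annotations

_DK_REGIONS = [
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
]

_SUBCORTICAL = [
    "amygdala",
    "caudate",
    "hippocampus",
    "pallidum",
    "accumbens",
    "putamen",
    "thalamus",
]


def cortical_labels() -> list[str]:
    """The 68 cortical labels (34 per hemisphere), left hemisphere first."""
    return [f"lh_{r}" for r in _DK_REGIONS] + [f"rh_{r}" for r in _DK_REGIONS]


def volumetric_labels() -> list[str]:
    """The 84 volumetric labels: 68 cortical + 14 subcortical + 2 cerebellar."""
    labels = cortical_labels()
    labels += [f"lh_{r}" for r in _SUBCORTICAL] + [f"rh_{r}" for r in _SUBCORTICAL]
    labels += ["lh_cerebellum", "rh_cerebellum"]
    return labels


def labels_for_measure(measure: str) -> list[str]:
    if measure == "thickness_mm":
        return cortical_labels()
    if measure == "volume_mm3":
        return volumetric_labels()
    raise ValueError(f"unknown measure {measure!r}")
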