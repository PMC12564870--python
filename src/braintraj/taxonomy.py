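"""Region taxonomy: the 95-structure roster, bilateral pairing, lobe groups.

The segmentation outputs 95 structures named by FreeSurfer/FastSurfer
convention: 45 bilateral pairs (90 lateralized names, aseg subcortical
labels like ``Left-Hippocampus`` plus DKT cortical labels like
``ctx-lh-parstriangularis``) and 5 midline structures. Bilateral pairs
share a human-readable ``bilateral_name`` (e.g. "Hippocampus") used in
all summary tables, and each bilateral/midline structure is assigned to
one of seven lobe groups used for reporting:

* subcortical - deep gray nuclei plus choroid plexus and ventral DC
* frontal / parietal / temporal / occipital / cingulate - cortical
  lobes (the insula is conventionally grouped with the temporal lobe)
* other - ventricles, CSF, brain stem, white matter compartments,
  cerebellum, WM hypointensities

A second, coarser "validation" grouping (frontal, parietal, temporal,
occipital, limbic, cerebellum) is used by the inter-pipeline agreement
report.
"""
from __future__ import annotations

from dataclasses import dataclass

from .core import ValidationError

LOBES = ("subcortical", "frontal", "parietal", "temporal", "occipital", "cingulate", "other")

# (bilateral display name, lobe, FreeSurfer stem, kind)
#   kind "aseg"  -> lateralized as Left-<stem> / Right-<stem>
#   kind "ctx"   -> lateralized as ctx-lh-<stem> / ctx-rh-<stem>
_BILATERAL = [
    ("Thalamus", "subcortical", "Thalamus", "aseg"),
    ("Caudate", "subcortical", "Caudate", "aseg"),
    ("Putamen", "subcortical", "Putamen", "aseg"),
    ("Pallidum", "subcortical", "Pallidum", "aseg"),
    ("Hippocampus", "subcortical", "Hippocampus", "aseg"),
    ("Amygdala", "subcortical", "Amygdala", "aseg"),
    ("Accumbens Area", "subcortical", "Accumbens-area", "aseg"),
    ("Ventral DC", "subcortical", "VentralDC", "aseg"),
    ("Choroid Plexus", "subcortical", "choroid-plexus", "aseg"),
    ("Caudal Middle Frontal", "frontal", "caudalmiddlefrontal", "ctx"),
    ("Rostral Middle Frontal", "frontal", "rostralmiddlefrontal", "ctx"),
    ("Superior Frontal", "frontal", "superiorfrontal", "ctx"),
    ("Lateral Orbitofrontal", "frontal", "lateralorbitofrontal", "ctx"),
    ("Medial Orbitofrontal", "frontal", "medialorbitofrontal", "ctx"),
    ("Pars Opercularis", "frontal", "parsopercularis", "ctx"),
    ("Pars Orbitalis", "frontal", "parsorbitalis", "ctx"),
    ("Pars Triangularis", "frontal", "parstriangularis", "ctx"),
    ("Precentral", "frontal", "precentral", "ctx"),
    ("Inferior Parietal", "parietal", "inferiorparietal", "ctx"),
    ("Superior Parietal", "parietal", "superiorparietal", "ctx"),
    ("Supramarginal", "parietal", "supramarginal", "ctx"),
    ("Paracentral", "parietal", "paracentral", "ctx"),
    ("Postcentral", "parietal", "postcentral", "ctx"),
    ("Precuneus", "parietal", "precuneus", "ctx"),
    ("Entorhinal", "temporal", "entorhinal", "ctx"),
    ("Fusiform", "temporal", "fusiform", "ctx"),
    ("Inferior Temporal", "temporal", "inferiortemporal", "ctx"),
    ("Middle Temporal", "temporal", "middletemporal", "ctx"),
    ("Superior Temporal", "temporal", "superiortemporal", "ctx"),
    ("Transverse Temporal", "temporal", "transversetemporal", "ctx"),
    ("Parahippocampal", "temporal", "parahippocampal", "ctx"),
    ("Insula", "temporal", "insula", "ctx"),
    ("Cuneus", "occipital", "cuneus", "ctx"),
    ("Lateral Occipital", "occipital", "lateraloccipital", "ctx"),
    ("Lingual", "occipital", "lingual", "ctx"),
    ("Pericalcarine", "occipital", "pericalcarine", "ctx"),
    ("Caudal Anterior Cingulate", "cingulate", "caudalanteriorcingulate", "ctx"),
    ("Isthmus Cingulate", "cingulate", "isthmuscingulate", "ctx"),
    ("Posterior Cingulate", "cingulate", "posteriorcingulate", "ctx"),
    ("Rostral Anterior Cingulate", "cingulate", "rostralanteriorcingulate", "ctx"),
    ("Cerebellum Cortex", "other", "Cerebellum-Cortex", "aseg"),
    ("Cerebellum White Matter", "other", "Cerebellum-White-Matter", "aseg"),
    ("Cerebral White Matter", "other", "Cerebral-White-Matter", "aseg"),
    ("Inf Lat Vent", "other", "Inf-Lat-Vent", "aseg"),
    ("Lateral Ventricle", "other", "Lateral-Ventricle", "aseg"),
]

# (name, lobe) for midline (non-bilateral) structures
_MIDLINE = [
    ("3rd Ventricle", "other", "3rd-Ventricle"),
    ("4th Ventricle", "other", "4th-Ventricle"),
    ("Brain Stem", "other", "Brain-Stem"),
    ("CSF", "other", "CSF"),
    ("WM Hypointensities", "other", "WM-hypointensities"),
]

# Coarse grouping used only by the inter-pipeline agreement report.
VALIDATION_GROUPING = {
    "Frontal lobe": [n for n, lobe, *_ in _BILATERAL if lobe == "frontal"],
    "Parietal lobe": [n for n, lobe, *_ in _BILATERAL if lobe == "parietal"],
    "Temporal lobe": [
        n for n, lobe, *_ in _BILATERAL if lobe == "temporal" and n not in ("Entorhinal", "Parahippocampal")
    ],
    "Occipital lobe": [n for n, lobe, *_ in _BILATERAL if lobe == "occipital"],
    "Limbic lobe": [
        "Hippocampus", "Amygdala", "Entorhinal", "Parahippocampal",
        "Caudal Anterior Cingulate", "Isthmus Cingulate",
        "Posterior Cingulate", "Rostral Anterior Cingulate",
    ],
    "Cerebellum": ["Cerebellum Cortex", "Cerebellum White Matter"],
}

# Common alternative spellings seen in FreeSurfer versions and reports.
NAME_ALIASES = {
    "Left-Thalamus-Proper": "Left-Thalamus",
    "Right-Thalamus-Proper": "Right-Thalamus",
    "Left-Inferior-Lateral-Ventricle": "Left-Inf-Lat-Vent",
    "Right-Inferior-Lateral-Ventricle": "Right-Inf-Lat-Vent",
    "Brain-Stem-Proper": "Brain-Stem",
    "WM-Hypointensities": "WM-hypointensities",
}


@dataclass(frozen=True)
class Region:
    """One of the 95 segmented structures."""

    name: str                 # canonical FreeSurfer-style label
    laterality: str           # left | right | midline
    bilateral_name: str       # shared display name of the L/R pair
    lobe: str                 # one of LOBES


def _lateralized(stem: str, kind: str, side: str) -> str:
    if kind == "aseg":
        return f"{'Left' if side == 'left' else 'Right'}-{stem}"
    return f"ctx-{'lh' if side == 'left' else 'rh'}-{stem}"


class RegionTaxonomy:
    """Catalogue of the 95 structures with pairing and lobe lookups."""

    def __init__(self):
        self.regions: list[Region] = []
        for display, lobe, stem, kind in _BILATERAL:
            for side in ("left", "right"):
                self.regions.append(Region(_lateralized(stem, kind, side), side, display, lobe))
        for display, lobe, canonical in _MIDLINE:
            self.regions.append(Region(canonical, "midline", display, lobe))
        self._by_name = {r.name: r for r in self.regions}
        self._pairs = {}
        for r in self.regions:
            self._pairs.setdefault(r.bilateral_name, {})[r.laterality] = r.name

    # -- lookups -----------------------------------------------------------
    @property
    def bilateral_names(self) -> list[str]:
        """The 50 bilateral/midline display names, in table (lobe) order."""
        seen, out = set(), []
        for lobe in LOBES:
            for r in self.regions:
                if r.lobe == lobe and r.bilateral_name not in seen:
                    seen.add(r.bilateral_name)
                    out.append(r.bilateral_name)
        return out

    @property
    def midline_names(self) -> list[str]:
        return [r.bilateral_name for r in self.regions if r.laterality == "midline"]

    def lobe_of(self, bilateral_name: str) -> str:
        sides = self._pairs.get(bilateral_name)
        if sides is None:
            raise ValidationError(f"unknown region: {bilateral_name!r}")
        return self._by_name[next(iter(sides.values()))].lobe

    def pair(self, bilateral_name: str) -> dict:
        """Map laterality -> canonical name for one bilateral/midline entry."""
        if bilateral_name not in self._pairs:
            raise ValidationError(f"unknown region: {bilateral_name!r}")
        return dict(self._pairs[bilateral_name])

    def is_midline(self, bilateral_name: str) -> bool:
        return "midline" in self.pair(bilateral_name)

    def normalize(self, raw_name: str) -> str:
        """Resolve aliases to the canonical lateralized label."""
        name = NAME_ALIASES.get(raw_name, raw_name)
        if name not in self._by_name:
            raise ValidationError(f"unrecognized structure name: {raw_name!r}")
        return name

    def __contains__(self, name: str) -> bool:
        return name in self._by_name or name in NAME_ALIASES

    def __len__(self) -> int:
        return len(self.regions)


_DEFAULT: RegionTaxonomy | None = None


def default_taxonomy() -> RegionTaxonomy:
    """Shared read-only taxonomy instance."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = RegionTaxonomy()
    return _DEFAULT
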