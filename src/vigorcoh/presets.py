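"""Named candidate sets and atlas labels.

Candidate sets restrict which spatial units enter the subject-specific
decoding models.  The two 21-unit presets mirror the left-central sensor
cluster and the bilateral fronto-parietal parcel set used in the main
analyses; ``all-channels`` means "no restriction".
"""

from __future__ import annotations

# Desikan-Killiany cortical parcel base names (34 per hemisphere -> 68).
_DK_BASE = [
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal", "middletemporal",
    "paracentral", "parahippocampal", "parsopercularis", "parsorbitalis",
    "parstriangularis", "pericalcarine", "postcentral", "posteriorcingulate",
    "precentral", "precuneus", "rostralanteriorcingulate",
    "rostralmiddlefrontal", "superiorfrontal", "superiorparietal",
    "superiortemporal", "supramarginal", "temporalpole", "transversetemporal",
]

DESIKAN_KILLIANY_PARCELS: list[str] = (
    [f"{name}-lh" for name in _DK_BASE] + [f"{name}-rh" for name in _DK_BASE]
)

#: The connectivity seed: left precentral gyrus (approximate left motor
#: cortex, contralateral to the moving right hand).
SEED_PARCEL = "precentral-lh"

#: 21 bilateral fronto-parietal parcels entering the source-space models
#: (precentral on the right only: the left precentral is the seed).
FRONTO_PARIETAL_21: list[str] = [
    "precuneus-lh", "precuneus-rh",
    "superiorparietal-lh", "superiorparietal-rh",
    "inferiorparietal-lh", "inferiorparietal-rh",
    "supramarginal-lh", "supramarginal-rh",
    "postcentral-lh", "postcentral-rh",
    "precentral-rh",
    "superiorfrontal-lh", "superiorfrontal-rh",
    "caudalmiddlefrontal-lh", "caudalmiddlefrontal-rh",
    "rostralmiddlefrontal-lh", "rostralmiddlefrontal-rh",
    "parsopercularis-lh", "parsopercularis-rh",
    "parstriangularis-lh", "parstriangularis-rh",
]

# Printed left-central channel list (BioSemi 128 labels).  The printed list
# repeats D18; the duplicate is dropped so candidate groups stay disjoint.
LEFT_CENTRAL_21: list[str] = [
    "D1", "D15", "D16", "D2", "D14", "D13", "D18", "D17", "D19", "D20",
    "D12", "D28", "D27", "D11", "D10", "D21", "D26", "D29", "A6", "A7",
]

#: C3-equivalent and adjacent electrodes (small left-central subset).
C3_CLUSTER: list[str] = ["D19", "D12", "D28", "D18", "D20"]

CANDIDATE_PRESETS: dict[str, "list[str] | None"] = {
    "left-central-21": LEFT_CENTRAL_21,
    "fronto-parietal-21": FRONTO_PARIETAL_21,
    "c3-cluster": C3_CLUSTER,
    "all-channels": None,
}


def resolve_candidates(name: "str | list[str]",
                       available: list[str]) -> list[str]:
    """Resolve a preset name (or explicit list) against available units.

    ``all-channels`` returns every available unit.  Preset members missing
    from ``available`` raise, except for ``all-channels``.
    """
    if isinstance(name, str):
        if name not in CANDIDATE_PRESETS:
            raise KeyError(
                f"unknown candidate preset {name!r}; "
                f"known: {sorted(CANDIDATE_PRESETS)}")
        preset = CANDIDATE_PRESETS[name]
        if preset is None:
            return list(available)
        wanted = preset
    else:
        wanted = list(name)
    missing = [u for u in wanted if u not in available]
    if missing:
        raise KeyError(f"candidate units not available: {missing}")
    return list(wanted)
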