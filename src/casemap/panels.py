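"""Disease ROI panels and bilateral region aliases.

Stats-file region names are kept verbatim; panels are expressed with short
field names ("caudate") that expand bilaterally through the alias table.
"""

from __future__ import annotations

#: Short panel name -> verbatim stats-file region names (bilateral).
REGION_ALIASES: dict[str, list[str]] = {
    "caudate": ["Left-Caudate", "Right-Caudate"],
    "putamen": ["Left-Putamen", "Right-Putamen"],
    "accumbens": ["Left-Accumbens-area", "Right-Accumbens-area"],
    "ventricles": ["Left-Lateral-Ventricle", "Right-Lateral-Ventricle"],
    "precentral": ["lh-precentral", "rh-precentral"],
    "postcentral": ["lh-postcentral", "rh-postcentral"],
    "superiorfrontal": ["lh-superiorfrontal", "rh-superiorfrontal"],
    "superiorparietal": ["lh-superiorparietal", "rh-superiorparietal"],
    "inferiorparietal": ["lh-inferiorparietal", "rh-inferiorparietal"],
    "insula": ["lh-insula", "rh-insula"],
    "medialorbitofrontal": ["lh-medialorbitofrontal", "rh-medialorbitofrontal"],
}

#: Huntington's disease panel: subcortical volumes and ventricles, cortical
#: thickness in motor/parietal/frontal/insular regions, plus global GM and WM.
HD_PANEL_SPEC: list[tuple[str, str]] = [
    ("caudate", "volume_mm3"),
    ("putamen", "volume_mm3"),
    ("accumbens", "volume_mm3"),
    ("ventricles", "volume_mm3"),
    ("precentral", "thickness_mm"),
    ("postcentral", "thickness_mm"),
    ("superiorfrontal", "thickness_mm"),
    ("superiorparietal", "thickness_mm"),
    ("inferiorparietal", "thickness_mm"),
    ("insula", "thickness_mm"),
    ("medialorbitofrontal", "thickness_mm"),
    ("global", "gm_total_mm3"),
    ("global", "wm_total_mm3"),
]

DISEASE_PANELS = {"hd": HD_PANEL_SPEC}


def expand_panel(panel_spec: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Expand short names bilaterally into (region, measure) biomarker keys."""
    keys: list[tuple[str, str]] = []
    for name, measure in panel_spec:
        regions = REGION_ALIASES.get(name, [name])
        for region in regions:
            keys.append((region, measure))
    return keys


def disease_panel(disease: str) -> list[tuple[str, str]]:
    """Materialized bilateral biomarker-key panel for a named disease."""
    spec = DISEASE_PANELS.get(disease.lower())
    if spec is None:
        raise ValueError(
            f"unknown disease {disease!r}; available: {sorted(DISEASE_PANELS)}"
        )
    return expand_panel(spec)
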