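"""The 24-node region-of-interest scheme (12 bilateral ROIs).

Sensorimotor cortical areas, basal-ganglia nuclei and the anterior/posterior
insula, each taken bilaterally.  Atlas labels are 1-based: ROI i (0-based) has
left-hemisphere label 2i+1 and right-hemisphere label 2i+2; graph node indices
are label-1.
"""

from __future__ import annotations

__all__ = ["ROI_NAMES", "ROI_SYSTEMS", "study_label_table", "node_name", "node_index"]

ROI_NAMES = (
    "M1",
    "S1",
    "SMA",
    "preSMA",
    "PMd",
    "caudate",
    "putamen",
    "pallidum",
    "thalamus",
    "accumbens",
    "anterior_insula",
    "posterior_insula",
)

ROI_SYSTEMS = {
    "M1": "sensorimotor",
    "S1": "sensorimotor",
    "SMA": "sensorimotor",
    "preSMA": "sensorimotor",
    "PMd": "sensorimotor",
    "caudate": "basal-ganglia",
    "putamen": "basal-ganglia",
    "pallidum": "basal-ganglia",
    "thalamus": "basal-ganglia",
    "accumbens": "basal-ganglia",
    "anterior_insula": "insula",
    "posterior_insula": "insula",
}

N_NODES = 24


def study_label_table() -> dict[int, tuple[str, str, str]]:
    """label -> (name, hemisphere, system) for the 24-label study atlas."""
    table = {}
    for i, name in enumerate(ROI_NAMES):
        system = ROI_SYSTEMS[name]
        table[2 * i + 1] = (name, "L", system)
        table[2 * i + 2] = (name, "R", system)
    return table


def node_name(node: int) -> str:
    """Graph node index (0-23) -> e.g. 'L_putamen'."""
    if not 0 <= node < N_NODES:
        raise ValueError(f"node index must be in [0, {N_NODES - 1}], got {node}")
    name, hemi, _ = study_label_table()[node + 1]
    return f"{hemi}_{name}"


def node_index(name: str) -> int:
    """'L_putamen' -> graph node index (0-23)."""
    for label, (roi, hemi, _) in study_label_table().items():
        if f"{hemi}_{roi}" == name:
            return label - 1
    raise KeyError(f"unknown ROI name: {name!r}")
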