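"""AAL-90 node atlas: the 90 cerebral regions (cerebellum excluded) that
define the nodes of the covariance network.

Nodes are numbered 1-90 in the conventional AAL order: odd numbers are
left-hemisphere regions, even numbers the right-hemisphere homologues.
Column names in cohort tables are the ``name`` field (e.g. ``Insula_L``).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

# (short AAL name stem, anatomical description) in node order; each stem
# expands to a left/right pair.
_AAL45: list[tuple[str, str]] = [
    ("Precentral", "Precentral gyrus"),
    ("Frontal_Sup", "Superior frontal gyrus, dorsolateral"),
    ("Frontal_Sup_Orb", "Superior frontal gyrus, orbital part"),
    ("Frontal_Mid", "Middle frontal gyrus"),
    ("Frontal_Mid_Orb", "Middle frontal gyrus, orbital part"),
    ("Frontal_Inf_Oper", "Inferior frontal gyrus, opercular part"),
    ("Frontal_Inf_Tri", "Inferior frontal gyrus, triangular part"),
    ("Frontal_Inf_Orb", "Inferior frontal gyrus, orbital part"),
    ("Rolandic_Oper", "Rolandic operculum"),
    ("Supp_Motor_Area", "Supplementary motor area"),
    ("Olfactory", "Olfactory cortex"),
    ("Frontal_Sup_Medial", "Superior frontal gyrus, medial"),
    ("Frontal_Med_Orb", "Superior frontal gyrus, medial orbital"),
    ("Rectus", "Gyrus rectus"),
    ("Insula", "Insula"),
    ("Cingulum_Ant", "Anterior cingulate gyrus"),
    ("Cingulum_Mid", "Middle cingulate gyrus"),
    ("Cingulum_Post", "Posterior cingulate gyrus"),
    ("Hippocampus", "Hippocampus"),
    ("ParaHippocampal", "Parahippocampal gyrus"),
    ("Amygdala", "Amygdala"),
    ("Calcarine", "Calcarine fissure and surrounding cortex"),
    ("Cuneus", "Cuneus"),
    ("Lingual", "Lingual gyrus"),
    ("Occipital_Sup", "Superior occipital gyrus"),
    ("Occipital_Mid", "Middle occipital gyrus"),
    ("Occipital_Inf", "Inferior occipital gyrus"),
    ("Fusiform", "Fusiform gyrus"),
    ("Postcentral", "Postcentral gyrus"),
    ("Parietal_Sup", "Superior parietal gyrus"),
    ("Parietal_Inf", "Inferior parietal gyrus"),
    ("SupraMarginal", "Supramarginal gyrus"),
    ("Angular", "Angular gyrus"),
    ("Precuneus", "Precuneus"),
    ("Paracentral_Lobule", "Paracentral lobule"),
    ("Caudate", "Caudate nucleus"),
    ("Putamen", "Lenticular nucleus, putamen"),
    ("Pallidum", "Lenticular nucleus, pallidum"),
    ("Thalamus", "Thalamus"),
    ("Heschl", "Heschl gyrus"),
    ("Temporal_Sup", "Superior temporal gyrus"),
    ("Temporal_Pole_Sup", "Temporal pole: superior temporal gyrus"),
    ("Temporal_Mid", "Middle temporal gyrus"),
    ("Temporal_Pole_Mid", "Temporal pole: middle temporal gyrus"),
    ("Temporal_Inf", "Inferior temporal gyrus"),
]


@dataclass(frozen=True)
class AtlasNode:
    index: int  # 1-based AAL node number
    name: str
    description: str
    hemisphere: str  # "L" or "R"


def aal90_nodes() -> list[AtlasNode]:
    """Return the 90 atlas nodes in AAL order (left before right per region)."""
    nodes = []
    for i, (stem, desc) in enumerate(_AAL45):
        nodes.append(AtlasNode(2 * i + 1, f"{stem}_L", desc, "L"))
        nodes.append(AtlasNode(2 * i + 2, f"{stem}_R", desc, "R"))
    return nodes


def aal90_labels() -> list[str]:
    """The 90 ROI column names (``Precentral_L`` ... ``Temporal_Inf_R``)."""
    return [n.name for n in aal90_nodes()]


def atlas_frame() -> pd.DataFrame:
    """Atlas as a DataFrame with columns index/name/description/hemisphere."""
    return pd.DataFrame([vars(n) for n in aal90_nodes()])
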