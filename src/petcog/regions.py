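"""AAL2-style region naming for the 120-parcel atlas."""

from __future__ import annotations

# 47 bilateral cerebral parcels + 9 bilateral cerebellar parcels + 8 vermis
# parcels = 47*2 + 9*2 + 8 = 120 labels, AAL2 ordering convention (L before R).
_BILATERAL = [
    "Precentral", "Frontal_Sup_2", "Frontal_Mid_2", "Frontal_Inf_Oper",
    "Frontal_Inf_Tri", "Frontal_Inf_Orb_2", "Rolandic_Oper", "Supp_Motor_Area",
    "Olfactory", "Frontal_Sup_Medial", "Frontal_Med_Orb", "Rectus", "OFCmed",
    "OFCant", "OFCpost", "OFClat", "Insula", "Cingulate_Ant", "Cingulate_Mid",
    "Cingulate_Post", "Hippocampus", "ParaHippocampal", "Amygdala", "Calcarine",
    "Cuneus", "Lingual", "Occipital_Sup", "Occipital_Mid", "Occipital_Inf",
    "Fusiform", "Postcentral", "Parietal_Sup", "Parietal_Inf", "SupraMarginal",
    "Angular", "Precuneus", "Paracentral_Lobule", "Caudate", "Putamen",
    "Pallidum", "Thalamus", "Heschl", "Temporal_Sup", "Temporal_Pole_Sup",
    "Temporal_Mid", "Temporal_Pole_Mid", "Temporal_Inf",
    "Cerebelum_Crus1", "Cerebelum_Crus2", "Cerebelum_3", "Cerebelum_4_5",
    "Cerebelum_6", "Cerebelum_7b", "Cerebelum_8", "Cerebelum_9", "Cerebelum_10",
]
_VERMIS = [
    "Vermis_1_2", "Vermis_3", "Vermis_4_5", "Vermis_6",
    "Vermis_7", "Vermis_8", "Vermis_9", "Vermis_10",
]

AAL2_REGIONS: tuple[str, ...] = tuple(
    f"{name}_{side}" for name in _BILATERAL for side in ("L", "R")
) + tuple(_VERMIS)

assert len(AAL2_REGIONS) == 120


def region_names(n_regions: int) -> list[str]:
    """Return ``n_regions`` region labels.

    The first 120 follow the AAL2 naming convention; beyond that, synthetic
    ``Region_<i>`` labels are appended (only relevant for toy configurations).
    """
    if n_regions <= len(AAL2_REGIONS):
        return list(AAL2_REGIONS[:n_regions])
    extra = [f"Region_{i}" for i in range(len(AAL2_REGIONS), n_regions)]
    return list(AAL2_REGIONS) + extra
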