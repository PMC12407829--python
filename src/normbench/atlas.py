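"""ROI name catalogues for the full-scale cohort emulation.

Cortical thickness is modeled on the Destrieux surface parcellation
(74 regions per hemisphere, 148 total) and subcortical volumes on a
19-region ASEG selection, giving the 167 regions modeled at full scale.
Smaller test cohorts use generic ``roi-###`` names.
"""

from __future__ import annotations

_DESTRIEUX_BASE = [
    "G_and_S_frontomargin",
    "G_and_S_occipital_inf",
    "G_and_S_paracentral",
    "G_and_S_subcentral",
    "G_and_S_transv_frontopol",
    "G_and_S_cingul-Ant",
    "G_and_S_cingul-Mid-Ant",
    "G_and_S_cingul-Mid-Post",
    "G_cingul-Post-dorsal",
    "G_cingul-Post-ventral",
    "G_cuneus",
    "G_front_inf-Opercular",
    "G_front_inf-Orbital",
    "G_front_inf-Triangul",
    "G_front_middle",
    "G_front_sup",
    "G_Ins_lg_and_S_cent_ins",
    "G_insular_short",
    "G_occipital_middle",
    "G_occipital_sup",
    "G_oc-temp_lat-fusifor",
    "G_oc-temp_med-Lingual",
    "G_oc-temp_med-Parahip",
    "G_orbital",
    "G_pariet_inf-Angular",
    "G_pariet_inf-Supramar",
    "G_parietal_sup",
    "G_postcentral",
    "G_precentral",
    "G_precuneus",
    "G_rectus",
    "G_subcallosal",
    "G_temp_sup-G_T_transv",
    "G_temp_sup-Lateral",
    "G_temp_sup-Plan_polar",
    "G_temp_sup-Plan_tempo",
    "G_temporal_inf",
    "G_temporal_middle",
    "Lat_Fis-ant-Horizont",
    "Lat_Fis-ant-Vertical",
    "Lat_Fis-post",
    "Pole_occipital",
    "Pole_temporal",
    "S_calcarine",
    "S_central",
    "S_cingul-Marginalis",
    "S_circular_insula_ant",
    "S_circular_insula_inf",
    "S_circular_insula_sup",
    "S_collat_transv_ant",
    "S_collat_transv_post",
    "S_front_inf",
    "S_front_middle",
    "S_front_sup",
    "S_interm_prim-Jensen",
    "S_intrapariet_and_P_trans",
    "S_oc_middle_and_Lunatus",
    "S_oc_sup_and_transversal",
    "S_occipital_ant",
    "S_oc-temp_lat",
    "S_oc-temp_med_and_Lingual",
    "S_orbital_lateral",
    "S_orbital_med-olfact",
    "S_orbital-H_Shaped",
    "S_parieto_occipital",
    "S_pericallosal",
    "S_postcentral",
    "S_precentral-inf-part",
    "S_precentral-sup-part",
    "S_suborbital",
    "S_subparietal",
    "S_temporal_inf",
    "S_temporal_sup",
    "S_temporal_transverse",
]

_ASEG_BILATERAL = [
    "Thalamus-Proper",
    "Caudate",
    "Putamen",
    "Pallidum",
    "Hippocampus",
    "Amygdala",
    "Accumbens-area",
    "VentralDC",
    "Cerebellum-Cortex",
]


def destrieux_names() -> list[str]:
    """148 cortical thickness ROI names (lh_/rh_ prefixed Destrieux labels)."""
    return [f"{hemi}_{name}" for hemi in ("lh", "rh") for name in _DESTRIEUX_BASE]


def aseg_names() -> list[str]:
    """19 subcortical volume ROI names (ASEG selection, bilateral + brainstem)."""
    names = [f"{side}-{name}" for side in ("Left", "Right") for name in _ASEG_BILATERAL]
    names.append("Brain-Stem")
    return names


def full_roi_names() -> list[str]:
    """All 167 modeled ROI names: 148 cortical + 19 subcortical."""
    return destrieux_names() + aseg_names()


def medial_temporal_rois(roi_names: list[str] | None = None) -> list[str]:
    """ROIs carrying the simulated AD atrophy effect.

    For the full atlas these are the classic medial-temporal AD signature:
    bilateral hippocampus, amygdala, parahippocampal and middle temporal
    gyri.  For generic ``roi-###`` cohorts the first tenth of the ROIs
    (at least one) stand in for the atrophy-bearing set.
    """
    if roi_names is None:
        roi_names = full_roi_names()
    signature = {
        "Left-Hippocampus",
        "Right-Hippocampus",
        "Left-Amygdala",
        "Right-Amygdala",
        "lh_G_oc-temp_med-Parahip",
        "rh_G_oc-temp_med-Parahip",
        "lh_G_temporal_middle",
        "rh_G_temporal_middle",
    }
    hits = [name for name in roi_names if name in signature]
    if hits:
        return hits
    k = max(1, len(roi_names) // 10)
    return list(roi_names[:k])


def generic_roi_names(n: int) -> list[str]:
    if n == len(_DESTRIEUX_BASE) * 2 + len(_ASEG_BILATERAL) * 2 + 1:
        return full_roi_names()
    return [f"roi-{i:03d}" for i in range(1, n + 1)]
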