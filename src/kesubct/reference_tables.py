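"""Published group-level summary statistics for the rat drill-hole study.

These are the printed group means (mean over n = 8 specimens) of the bone
and vascular structural indices for rat tibial drill-hole defects under
hindlimb unloading (HU), unloading with deferoxamine (DFOHU) and weight
bearing (WB), at postoperative days 5 and 10, plus the vessel-size-specific
breakdowns over the five diameter classes. They serve as inputs to the
reporting arithmetic: percent contrasts between group means, and the check
that the size-specific values partition the totals.
"""

from __future__ import annotations

#: Table of index means per group (day-5 groups: HU5/DFOHU5/WB5; day-10:
#: HU10/DFOHU10/WB10). Units: B.Vf/V.Vf %, B.Th/V.D um, B.Seg/V.Seg /mm^3.
INDEX_MEANS = {
    "B.Vf_pct":      {"HU5": 0.18, "DFOHU5": 0.54, "WB5": 1.44,
                      "HU10": 26.15, "DFOHU10": 37.14, "WB10": 45.32},
    "V.Vf_pct":      {"HU5": 4.48, "DFOHU5": 9.08, "WB5": 6.57,
                      "HU10": 4.61, "DFOHU10": 6.05, "WB10": 7.06},
    "B.Th_um":       {"HU5": 15.08, "DFOHU5": 16.84, "WB5": 11.80,
                      "HU10": 21.59, "DFOHU10": 26.89, "WB10": 34.81},
    "V.D_um":        {"HU5": 20.20, "DFOHU5": 20.93, "WB5": 19.64,
                      "HU10": 17.25, "DFOHU10": 18.07, "WB10": 19.87},
    "B.Seg_per_mm3": {"HU5": 117, "DFOHU5": 470, "WB5": 3388,
                      "HU10": 40413, "DFOHU10": 32531, "WB10": 16777},
    "V.Seg_per_mm3": {"HU5": 1796, "DFOHU5": 2911, "WB5": 2401,
                      "HU10": 2183, "DFOHU10": 2830, "WB10": 2873},
}

#: Vessel-size-specific V.Vf (%) per diameter class (<10, 10-20, 20-30,
#: 30-40, >=40 um), per group.
SIZE_SPECIFIC_VVF = {
    "HU5":     [0.03, 1.23, 1.05, 0.88, 1.28],
    "DFOHU5":  [0.06, 3.33, 2.93, 1.59, 1.16],
    "WB5":     [0.04, 2.42, 2.05, 1.39, 0.67],
    "HU10":    [0.06, 2.21, 1.63, 0.44, 0.04],
    "DFOHU10": [0.04, 2.58, 1.91, 0.76, 0.11],
    "WB10":    [0.03, 2.54, 2.85, 1.23, 0.41],
}

#: Vessel-size-specific V.Seg (/mm^3) per diameter class, per group.
SIZE_SPECIFIC_VSEG = {
    "HU5":     [73.5, 838.6, 453.6, 225.7, 204.9],
    "DFOHU5":  [119.7, 1516.3, 747.7, 329.6, 197.4],
    "WB5":     [84.9, 1225.3, 602.5, 329.6, 159.1],
    "HU10":    [114.9, 1290.4, 581.9, 182.4, 13.7],
    "DFOHU10": [73.8, 1715.9, 728.3, 265.6, 46.4],
    "WB10":    [68.5, 1453.3, 898.7, 363.7, 89.2],
}
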