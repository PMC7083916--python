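"""Packaged drift-tube CCS reference values for the HS standard library.

The registry built from this module holds the 36 defined heparan-sulfate
standards (#1-#36) plus the two natural hexasaccharides #HS1/#HS2, with
every precursor and fragment CCS value published for them in the
main-text results of the originating study (helium drift-tube values,
stored as printed, in integer Å^2).  Standards whose full structure or
CCS was only reported in supplementary material are present in the
roster without a sequence or without CCS entries — absent, not guessed.
"""

# standard_id -> (grammar string or None, description)
STANDARD_SEQUENCES = {
    "#1": ("dUA-GlcNAc", "disaccharide"),
    "#2": ("dUA-GlcNAc6S", "disaccharide"),
    "#3": (None, "disaccharide (structure not in main text)"),
    "#4": ("dUA-GlcNS6S", "disaccharide"),
    "#5": ("dUA2S-GlcNS", "disaccharide"),
    "#6": (None, "disaccharide (structure not in main text)"),
    "#7": ("dUA2S-GlcNAc", "disaccharide"),
    "#8": (None, "disaccharide (structure not in main text)"),
    "#9": ("GlcA-GlcNAc6S-GlcA-GlcNAc6S-R1", "homogeneous GlcA tetrasaccharide"),
    "#10": ("IdoA-GlcNAc6S-IdoA-GlcNAc6S-R1", "homogeneous IdoA tetrasaccharide"),
    "#11": ("GlcA-GlcNAc6S-IdoA-GlcNAc6S-R1", "heterogeneous tetrasaccharide"),
    "#12": ("GlcA-GlcNS6S-IdoA-GlcNS6S-R1", "heterogeneous NS tetrasaccharide"),
    "#13": ("IdoA-GlcNAc6S-GlcA-GlcNAc6S-R1", "heterogeneous tetrasaccharide"),
    "#14": ("IdoA-GlcNS6S-GlcA-GlcNS6S-R1", "heterogeneous NS tetrasaccharide"),
    "#15": ("GlcA-GlcNS6S-IdoA2S-GlcNS6S-R1", "2S tetrasaccharide"),
    "#16": (
        "GlcA-GlcNS6S-IdoA-GlcNS6S-GlcA-GlcNS6S-R1",
        "hexasaccharide extending #14",
    ),
    "#17": ("GlcNAc6S-[GlcA-GlcNAc6S]2-GlcA-R2", "homogeneous GlcA hexasaccharide"),
    "#18": ("GlcNAc6S-[IdoA-GlcNAc6S]2-IdoA-R2", "homogeneous IdoA hexasaccharide"),
    "#19": ("GlcNAc6S-[IdoA-GlcNAc6S]3-IdoA-R2", "homogeneous IdoA octasaccharide"),
    "#20": ("GlcNAc6S-[GlcA-GlcNAc6S]3-GlcA-R2", "homogeneous GlcA octasaccharide"),
    "#21": (None, "heterogeneous octasaccharide (structure not in main text)"),
    "#22": (None, "heterogeneous octasaccharide (structure not in main text)"),
    "#23": (None, "heterogeneous octasaccharide (structure not in main text)"),
    "#24": (None, "heterogeneous octasaccharide (structure not in main text)"),
    "#25": (
        "GlcA-GlcNS-GlcA-GlcNS-IdoA-GlcNS-GlcA-GlcNS-GlcA-R3",
        "nonasaccharide",
    ),
    "#26": (
        "GlcA-GlcNS-GlcA-GlcNS-IdoA2S-GlcNS-GlcA-GlcNS-GlcA-R3",
        "nonasaccharide with single 2S",
    ),
    "#27": ("GlcNAc6S-[IdoA-GlcNAc6S]4-IdoA-R2", "homogeneous IdoA decasaccharide"),
    "#28": ("GlcNAc6S-[GlcA-GlcNAc6S]4-GlcA-R2", "homogeneous GlcA decasaccharide"),
    "#29": ("dUA2S-GlcNS3S6S", "trisulfated disaccharide"),
    "#30": ("dUA-GlcNS-IdoA2S-GlcNS3S", "porcine ATIII-site tetrasaccharide"),
    "#31": ("dUA-GlcNS6S-GlcA-GlcNS3S6S", "porcine ATIII-site tetrasaccharide"),
    "#32": ("dUA-GlcNAc6S-GlcA-GlcNS3S6S", "bovine ATIII-site tetrasaccharide"),
    "#33": ("GlcA-GlcNS6S-GlcA-GlcNS6S-IdoA2S-GlcNS6S-R1", "6S hexasaccharide"),
    "#34": ("GlcA-GlcNS6S-GlcA-GlcNS3S-IdoA2S-GlcNS6S-R1", "3S hexasaccharide"),
    "#35": ("GlcA-GlcNS6S-GlcA-GlcNS3S6S-IdoA2S-GlcNS6S-R1", "3S6S hexasaccharide"),
    # Heparinase-II product of #26 retaining the reducing-end tag; the
    # non-reducing end carries the single 2S on the unsaturated side.
    "#36": ("dUA-GlcNS-IdoA2S-GlcNS-GlcA-GlcNS-GlcA-R3", "7mer with single 2S"),
    "#HS1": ("dUA-GlcNS-IdoA2S-GlcNS-GlcA-GlcNAc", "FGF2-inhibitory hexasaccharide"),
    "#HS2": (
        "dUA-GlcNS-IdoA2S-GlcNS6S-GlcA-GlcNAc6S",
        "FGF2-inhibitory hexasaccharide",
    ),
}

# standard_id -> precursor CCS (Å^2, as printed)
PRECURSOR_CCS = {
    "#1": 112,
    "#2": 121,
    "#4": 123,
    "#5": 124,
    "#7": 124,
    "#9": 214,
    "#10": 242,
    "#11": 232,
    "#12": 236,
    "#13": 245,
    "#14": 234,
    "#15": 239,
    "#16": 259,
    "#17": 297,
    "#18": 292,
    "#25": 437,
    "#26": 441,
    "#27": 536,
    "#28": 524,
    "#29": 150,
    "#30": 228,
    "#31": 229,
    "#32": 234,
    "#33": 280,
    "#34": 282,
    "#35": 328,
}

# (standard_id, fragment label, CCS Å^2, provenance tag)
FRAGMENT_CCS = [
    ("#12", "B2", 135, "hexamer-overlay"),
    ("#12", "B3", 160, "hexamer-overlay"),
    ("#14", "Y2", 156, "hexamer-overlay"),
    ("#14", "Y3", 213, "hexamer-overlay"),
    ("#16", "B2", 135, "hexamer-overlay"),
    ("#16", "B3", 160, "hexamer-overlay"),
    ("#16", "Y2", 156, "hexamer-overlay"),
    ("#16", "Y3", 213, "hexamer-overlay"),
    ("#33", "B4", 225, "atiii-isomers"),
    ("#34", "B4", 220, "atiii-isomers"),
    ("#30", "B4", 218, "fgf-epitopes"),
    ("#36", "B1", 71, "fgf-epitopes"),
    ("#36", "B2", 110, "fgf-epitopes"),
    ("#36", "B3", 162, "fgf-epitopes"),
    ("#36", "B4", 201, "fgf-epitopes"),
    ("#HS1", "B1", 71, "fgf-epitopes"),
    ("#HS1", "B2", 110, "fgf-epitopes"),
    ("#HS1", "B3", 162, "fgf-epitopes"),
    ("#HS1", "B4", 201, "fgf-epitopes"),
    ("#HS2", "B4", 225, "fgf-epitopes"),
]

PRECURSOR_PROVENANCE = "intact-standards"
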