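"""Shared vocabulary of the pipeline: tissue categories, histology patch
classes, IHC markers and the color codes used by the synthetic renderer.

The synthetic H&E renderer paints every zone with a flat, class-specific
color. The offsets between class colors are small on screen but exactly
decodable, which lets the classifier contracts (normally trained CNNs) be
satisfied by simple color decoders on synthetic data.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# Tissue categories (32-px micro-patch classifier vocabulary)

TISSUE_CATEGORIES = ("Tissue", "Submucosa", "Muscle", "Background")
INFORMATIVE_CATEGORIES = frozenset({"Tissue", "Submucosa"})
NON_INFORMATIVE_CATEGORIES = frozenset({"Muscle", "Background"})

# ---------------------------------------------------------------------------
# Histology patch classes (k-means phenotype vocabulary)

INVOLVED_CLASSES = (
    "Inflammatory",
    "Crypt Dropout",
    "Crypt Dilation",
    "Distorted Glands",
)
UNINVOLVED_CLASSES = ("Crypts", "Lightly Packed", "Rosettes")
ALL_CLASSES = INVOLVED_CLASSES + UNINVOLVED_CLASSES

# ---------------------------------------------------------------------------
# IHC markers, in serial-section staining order (slide 1 is H&E)

MARKERS = ("CD8b", "CD3", "CD4")

#: Pseudo-multiplex overlay palette; draw order is the tuple order of MARKERS.
MARKER_PALETTE = {
    "CD8b": (255, 40, 40),
    "CD3": (40, 90, 255),
    "CD4": (255, 200, 0),
}

# ---------------------------------------------------------------------------
# Synthetic color codes (RGB, uint8)

WHITE = (255, 255, 255)
CATEGORY_COLORS = {
    "Background": WHITE,
    "Muscle": (150, 110, 160),
    "Submucosa": (235, 180, 215),
}

# Involved classes share R/B; the green channel encodes the class index.
# Uninvolved classes live on a visibly lighter pink ramp.
CLASS_COLORS = {
    "Inflammatory": (186, 96, 168),
    "Crypt Dropout": (186, 108, 168),
    "Crypt Dilation": (186, 120, 168),
    "Distorted Glands": (186, 132, 168),
    "Crypts": (210, 150, 192),
    "Lightly Packed": (210, 162, 192),
    "Rosettes": (210, 174, 192),
}

#: Pale hematoxylin counterstain of the synthetic IHC sections.
IHC_BACKGROUND = (232, 226, 242)

#: Hematoxylin crystal artifact specks: near-black in every channel (<30/255).
ARTIFACT_COLOR = (18, 16, 20)

#: Canonical DAB brown at the concentration the synthetic blobs are rendered
#: with (0.25 under the Ruifrok–Johnston H-E-D stain matrix as scaled by
#: skimage.color.hed2rgb). Round-trips through rgb2hed to DAB ~ 0.25.
DAB_RGB = (100, 36, 17)


def class_color_array() -> np.ndarray:
    """(7, 3) float array of class colors, ordered as ALL_CLASSES."""
    return np.array([CLASS_COLORS[c] for c in ALL_CLASSES], dtype=float)


def is_involved(class_name: str) -> bool:
    return class_name in INVOLVED_CLASSES
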