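"""Functional-network naming and ordering conventions.

The corpus callosum is parcellated by its connections to the cortical
resting-state networks of the 7- (or 17-) network functional atlas. Label
integers follow the atlas convention (1..K, 0 = background):

7-network order: VIS, SM, DA, VA, LN, FPN, DMN.

The anterior->posterior order used to lay out ground-truth crossing zones in
the phantom follows the midsagittal topography of the real parcellation:
limbic and default-mode fibers cross through the rostrum/genu, frontoparietal,
ventral-attention and somatomotor fibers through the body, dorsal-attention
and visual fibers through the splenium.
"""

from __future__ import annotations

YEO7_NAMES: tuple[str, ...] = ("VIS", "SM", "DA", "VA", "LN", "FPN", "DMN")

YEO17_NAMES: tuple[str, ...] = (
    "VisCent", "VisPeri", "SomMotA", "SomMotB", "DorsAttnA", "DorsAttnB",
    "SalVentAttnA", "SalVentAttnB", "LimbicB", "LimbicA", "ContA", "ContB",
    "ContC", "DefaultA", "DefaultB", "DefaultC", "TempPar",
)

# label ids ordered anterior -> posterior along the callosal midline
ANTERIOR_TO_POSTERIOR_7: tuple[int, ...] = (5, 7, 6, 4, 2, 3, 1)  # LN DMN FPN VA SM DA VIS

DIFFUSION_INDICES: tuple[str, ...] = ("FA", "MD", "RD", "AD")


def network_names(k: int) -> tuple[str, ...]:
    if k == 7:
        return YEO7_NAMES
    if k == 17:
        return YEO17_NAMES
    raise ValueError(f"supported network counts are 7 and 17, got {k}")


def anterior_order(k: int) -> tuple[int, ...]:
    """Label ids in anterior->posterior crossing order."""
    if k == 7:
        return ANTERIOR_TO_POSTERIOR_7
    if k == 17:
        return tuple(range(1, 18))
    raise ValueError(f"supported network counts are 7 and 17, got {k}")
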