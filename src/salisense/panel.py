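"""The 12-receptor sensing panel.

Each spot on the paper device carries one chemistry — a metal porphyrazine,
a pH indicator mixed with tetrabutylammonium hydroxide (TBOH) or
phenylboronic acid (PBA), or a coated silver nanoparticle (AgNP).  A receptor
responds (changes colour) only for the participant groups listed in
``responsive_to``; two receptors additionally carry a quantitative link to
fasting blood glucose (FBG): methyl red + TBOH (S5) tracks binned FBG
categories and thiomalic-acid-capped AgNPs (S10) track raw FBG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DIABETIC = "diabetic"
NONDIABETIC = "nondiabetic"
GROUPS = (DIABETIC, NONDIABETIC)

CHEMISTRIES = ("porphyrazine", "dye_TBOH", "dye_PBA", "AgNP")


@dataclass(frozen=True)
class ReceptorSpec:
    """Identity and phenomenological response profile of one sensing spot.

    Parameters
    ----------
    index : 1-based spot position S1..S12.
    chemistry : one of ``porphyrazine``, ``dye_TBOH``, ``dye_PBA``, ``AgNP``.
    responsive_to : groups whose saliva discolours this spot.
    fbg_rho : latent Pearson correlation between the spot's response
        magnitude and FBG (0 for uncorrelated receptors).
    fbg_link : which FBG representation the latent couples to when
        ``fbg_rho != 0`` — the raw value (``"raw"``) or the midpoint of the
        clinical FBG category (``"binned"``).
    baseline_rgb : unreacted spot colour, 0-255.
    max_delta_rgb : per-channel ceiling of the colour change, 0-255; the
        triple also fixes the relative R:G:B pattern of the response.
    """

    index: int
    name: str
    chemistry: str
    responsive_to: frozenset = field(default_factory=frozenset)
    fbg_rho: float = 0.0
    baseline_rgb: tuple = (128, 128, 128)
    max_delta_rgb: tuple = (0, 0, 0)
    fbg_link: str = "raw"

    def __post_init__(self):
        if not 1 <= self.index <= 12:
            raise ValueError(f"receptor index must be 1..12, got {self.index}")
        if self.chemistry not in CHEMISTRIES:
            raise ValueError(f"unknown chemistry {self.chemistry!r}")
        if not self.responsive_to <= set(GROUPS):
            raise ValueError(f"responsive_to must be a subset of {GROUPS}")
        if not -1.0 <= self.fbg_rho <= 1.0:
            raise ValueError("fbg_rho must lie in [-1, 1]")
        if self.fbg_link not in ("raw", "binned"):
            raise ValueError("fbg_link must be 'raw' or 'binned'")
        for t in (self.baseline_rgb, self.max_delta_rgb):
            if len(t) != 3 or not all(0 <= v <= 255 for v in t):
                raise ValueError("RGB triples must have 3 entries in [0, 255]")

    def responds_to(self, group: str) -> bool:
        return group in self.responsive_to


def _r(index, name, chemistry, responsive, rho, baseline, max_delta, link="raw"):
    return ReceptorSpec(index, name, chemistry, frozenset(responsive), rho,
                        baseline, max_delta, link)


#: Responsiveness pattern of the device: Zn-Pa (S2), MR+TBOH (S5), MB+PBA (S9)
#: and TMA-AgNPs (S10) respond to both groups; Cu-Pa (S3) only to
#: non-diabetic saliva; BP+PBA (S7), BR+PBA (S8) and CS-AgNPs (S12) only to
#: diabetic saliva; Co-Pa, TB+TBOH, BB+TBOH and Arg-AgNPs do not respond.
#: Baselines of the strongly responsive spots sit near an intensity extreme
#: so the full calibrated colour shift stays renderable without clipping.
DEFAULT_PANEL = (
    _r(1, "Co-Pa", "porphyrazine", (), 0.0, (64, 96, 168), (90, 70, 40)),
    _r(2, "Zn-Pa", "porphyrazine", GROUPS, 0.0, (30, 45, 50), (100, 90, 85)),
    _r(3, "Cu-Pa", "porphyrazine", (NONDIABETIC,), 0.0, (45, 35, 50), (100, 110, 55)),
    _r(4, "TB+TBOH", "dye_TBOH", (), 0.0, (40, 80, 140), (80, 90, 60)),
    _r(5, "MR+TBOH", "dye_TBOH", GROUPS, 0.726, (190, 80, 70), (120, 60, 36), "binned"),
    _r(6, "BB+TBOH", "dye_TBOH", (), 0.0, (80, 60, 130), (70, 80, 60)),
    _r(7, "BP+PBA", "dye_PBA", (DIABETIC,), 0.0, (54, 25, 54), (85, 125, 70)),
    _r(8, "BR+PBA", "dye_PBA", (DIABETIC,), 0.0, (54, 20, 25), (110, 95, 80)),
    _r(9, "MB+PBA", "dye_PBA", GROUPS, 0.0, (20, 25, 54), (85, 95, 100)),
    _r(10, "TMA-AgNPs", "AgNP", GROUPS, 0.871, (210, 190, 60), (130, 104, 52)),
    _r(11, "Arg-AgNPs", "AgNP", (), 0.0, (220, 200, 90), (90, 85, 60)),
    _r(12, "CS-AgNPs", "AgNP", (DIABETIC,), 0.0, (230, 210, 40), (115, 105, 58)),
)


def validate_panel(panel) -> None:
    """Check the panel covers indices 1..12 exactly once."""
    panel = tuple(panel)
    if len(panel) != 12:
        raise ValueError(f"panel must hold exactly 12 receptors, got {len(panel)}")
    indices = sorted(r.index for r in panel)
    if indices != list(range(1, 13)):
        raise ValueError("panel receptor indices must cover 1..12 uniquely")


#: Column labels of the 36-feature response matrix, receptor-major.
FEATURE_COLUMNS = tuple(f"S{i}_{c}" for i in range(1, 13) for c in "RGB")
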