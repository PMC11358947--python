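"""Standard 64-channel 10-20 montage used by the acquisition cap.

The channel list mirrors a 64-electrode actiCHamp layout with Fz as the
online reference and TP9/TP10 over the mastoids.  Scalp regions are named
by electrode-label prefix and are used by the synthetic generator to place
topographically localised band-power effects.
"""

from __future__ import annotations

# 64 labels, unique, 10-20/10-10 nomenclature.
CHANNELS_64: tuple[str, ...] = (
    "Fp1", "Fp2",
    "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10",
    "AF7", "AF3", "AF4", "AF8",
    "F5", "F1", "F2", "F6",
    "FT9", "FT7", "FC3", "FC4", "FT8", "FT10",
    "C5", "C1", "C2", "C6",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "P5", "P1", "P2", "P6",
    "PO7", "PO3", "POz", "PO4", "PO8",
)

# Channels dropped by the default selection policy: the online reference and
# the electrodes most contaminated by ocular / mastoid activity.
DROP_DEFAULT: frozenset[str] = frozenset({"Fz", "Fp1", "Fp2", "TP9", "TP10"})

MASTOIDS: tuple[str, str] = ("TP9", "TP10")

# Region groups by label prefix (matched against the channel name start).
REGION_PREFIXES: dict[str, tuple[str, ...]] = {
    "frontal": ("Fp", "AF", "F"),
    "central": ("FC", "FT", "C", "T"),
    "parietal": ("CP", "TP", "P"),
    "occipital": ("PO", "O"),
}


def region_mask(channel_names: list[str] | tuple[str, ...], regions: tuple[str, ...]):
    """Boolean mask over *channel_names* for channels in any named region."""
    import numpy as np

    prefixes: list[str] = []
    for r in regions:
        try:
            prefixes.extend(REGION_PREFIXES[r])
        except KeyError:
            raise ValueError(f"unknown region {r!r}") from None
    # longest-prefix match so e.g. "FC5" is central, not frontal
    all_prefixes = sorted(
        ((p, reg) for reg, ps in REGION_PREFIXES.items() for p in ps),
        key=lambda t: -len(t[0]),
    )
    wanted = set(regions)
    out = []
    for name in channel_names:
        reg = next((rg for p, rg in all_prefixes if name.startswith(p)), None)
        out.append(reg in wanted)
    return np.asarray(out, dtype=bool)
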