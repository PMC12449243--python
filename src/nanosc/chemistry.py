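"""Chemistry profiles describing the 10X read structure on long reads.

A profile captures everything the extractor needs to know about a library
preparation: the adapter searched at the read start, the cell-barcode and
UMI lengths that follow it, and how tolerant the adapter search should be
to nanopore indel errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# Partial 10X read-1 primer, the constant sequence preceding the cell barcode.
TENX_R1_ADAPTER = "CTACACGACGCTCTTCCGATCT"


@dataclass(frozen=True)
class ChemistryProfile:
    """Read-structure parameters for one library chemistry.

    Parameters
    ----------
    name:
        Profile identifier, e.g. ``"10x-3p-v3"``.
    adapter:
        Constant sequence expected immediately before the cell barcode.
    barcode_length, umi_length:
        Lengths (nt) of the cell barcode and UMI following the adapter.
    polyt_min_run:
        Minimum length for a stretch of T's after the UMI to count as the
        oligo-dT tail.
    max_adapter_edit_distance:
        Maximum semi-global edit distance (substitutions + indels) allowed
        when locating the adapter; indel tolerance matters for ONT reads.
    search_window:
        Number of bases from the read start searched for the adapter.
    """

    name: str
    adapter: str = TENX_R1_ADAPTER
    barcode_length: int = 16
    umi_length: int = 12
    polyt_min_run: int = 10
    max_adapter_edit_distance: int = 3
    search_window: int = 100

    def __post_init__(self) -> None:
        if self.barcode_length <= 0 or self.umi_length <= 0:
            raise ValueError("barcode_length and umi_length must be positive")
        min_window = len(self.adapter) + self.barcode_length + self.umi_length
        if self.search_window < min_window:
            raise ValueError(
                f"search_window ({self.search_window}) must cover adapter + "
                f"barcode + UMI ({min_window} nt)"
            )


#: Built-in profiles. 3' v3 kits carry a 12 nt UMI; 5' kits a 10 nt UMI.
PROFILES: dict[str, ChemistryProfile] = {
    "10x-3p-v3": ChemistryProfile(name="10x-3p-v3", umi_length=12),
    "10x-5p": ChemistryProfile(name="10x-5p", umi_length=10),
}


def get_profile(name: str) -> ChemistryProfile:
    try:
        return PROFILES[name]
    except KeyError:
        known = ", ".join(sorted(PROFILES))
        raise KeyError(f"unknown chemistry {name!r}; known profiles: {known}") from None
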