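"""Reference linker windows assembled from published motif states.

Two junctions of the intermicrovillar cadherins have fully printed motif
states and serve as fixed classifier inputs:

* the mouse PCDH24 EC2-3 linker, where the site-1 DXE element is replaced
  by SYN at residues 172-174 and the boundary motif is the DXPDL variant
  at residues 213-217 (site 3 coordinated through a backbone carbonyl) —
  a noncanonical junction binding 2 calcium ions;
* a fully canonical EC1-2 junction of the human CDHR5 type, carrying all
  five acidic elements (XEX, DXD, D(R/Y)(D/E), XDX, DXNDN) — 3 ions.

Residues not constrained by the printed motif states are filled with
neutral (non-acidic, non-N/P) residues, so classification is driven by
the motif states alone.  Coordinates follow processed-protein numbering.
"""

from __future__ import annotations

from .sequence_annotation import LinkerAnnotation, classify_linker

__all__ = [
    "mm_pcdh24_ec23_window",
    "hs_cdhr5_ec12_window",
    "classify_mm_pcdh24_ec23",
    "classify_hs_cdhr5_ec12",
]

_FILLER = "GSTAKLVMGSTAKLVMGSTAKLVMGSTAKLVM"  # neutral, motif-inert


def _fill(n: int, phase: int = 0) -> str:
    s = (_FILLER * (n // len(_FILLER) + 2))[phase : phase + n]
    return s


def mm_pcdh24_ec23_window() -> tuple[str, tuple[int, int]]:
    """Window spanning residues 160-225 of the processed mouse PCDH24
    sequence with the printed motif states: 172SYN174 in the site-1 slot
    and the 213DXPDL217 boundary, with the intervening site-2/3 elements
    (DXD, D(R/Y)(D/E), XDX) intact."""
    start, end = 160, 225
    slots = {
        172: "SYN",  # degenerate site-1 (canonical DXE lost)
        188: "DAD",  # DXD
        195: "DRE",  # D(R/Y)(D/E)
        205: "LDV",  # XDX
        213: "DMPDL",  # DXPDL-class boundary variant
    }
    window = list(_fill(end - start + 1))
    for pos, text in slots.items():
        off = pos - start
        window[off : off + len(text)] = list(text)
    return "".join(window), (start, end)


def hs_cdhr5_ec12_window() -> tuple[str, tuple[int, int]]:
    """Fully canonical EC1-2 junction window (human CDHR5 type): all five
    elements present with acidic residues at the required positions.  The
    repeat boundary (DXNDN end) is placed at residue 101."""
    start, end = 77, 116
    slots = {
        79: "IEL",  # XEX
        85: "DAD",  # DXD
        90: "DRE",  # D(R/Y)(D/E)
        94: "LDV",  # XDX
        97: "DVNDN",  # boundary
    }
    window = list(_fill(end - start + 1, phase=3))
    for pos, text in slots.items():
        off = pos - start
        window[off : off + len(text)] = list(text)
    return "".join(window), (start, end)


def classify_mm_pcdh24_ec23() -> LinkerAnnotation:
    window, pos = mm_pcdh24_ec23_window()
    return classify_linker(window, pos, upstream_repeat_index=2)


def classify_hs_cdhr5_ec12() -> LinkerAnnotation:
    window, pos = hs_cdhr5_ec12_window()
    return classify_linker(window, pos, upstream_repeat_index=1)
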