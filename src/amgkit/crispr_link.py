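"""CRISPR repeat-spacer detection and spacer-to-phage matching.

Hosts archive fragments of phage DNA as spacers between identical repeats
in CRISPR arrays; a spacer matching a phage contig links that host to the
phage.  Detection here is a simplified repeat scanner requiring exact
tandem repeat copies (19-38 bp) separated by spacers (19-48 bp), at least
three copies per array.  Matching follows the strict hit rule: the full
spacer must align (100% coverage) with at most two mismatches, no indels
(Hamming distance), on either strand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seq_io import reverse_complement

__all__ = [
    "CrisprArray",
    "SpacerMatch",
    "find_repeat_arrays",
    "match_spacers",
]


@dataclass(frozen=True)
class CrisprArray:
    contig_id: str
    start: int  # 1-based position of the first repeat copy
    repeat: str
    spacers: tuple[str, ...]

    @property
    def n_repeats(self) -> int:
        return len(self.spacers) + 1

    @property
    def end(self) -> int:  # 1-based inclusive
        return self.start + self.span - 1

    @property
    def span(self) -> int:
        return self.n_repeats * len(self.repeat) + sum(len(s) for s in self.spacers)


@dataclass(frozen=True)
class SpacerMatch:
    spacer_id: str
    contig_id: str
    position: int  # 1-based start on the forward strand
    strand: str  # '+' or '-'
    mismatches: int

    def __post_init__(self) -> None:
        if self.mismatches < 0:
            raise ValueError("negative mismatch count")


def find_repeat_arrays(
    genome: str,
    contig_id: str = "genome",
    repeat_len_range: tuple[int, int] = (19, 38),
    spacer_len_range: tuple[int, int] = (19, 48),
    min_repeats: int = 3,
) -> list[CrisprArray]:
    """Detect arrays of >= ``min_repeats`` exact tandem repeat copies.

    A candidate is a repeat unit within the length window whose successive
    occurrences are separated by spacer-window gaps; spacers are the
    inter-repeat segments (n repeats give n-1 spacers).  Among overlapping
    candidates (shifted or truncated re-detections of the same repeat) the
    one with the most copies wins, then the longer repeat unit, then the
    earlier start.
    """
    genome = genome.upper()
    n = len(genome)
    candidates: list[tuple[int, list[int], str, int]] = []  # start, chain, mer, rl

    rl_hi = min(repeat_len_range[1], n)
    for rl in range(rl_hi, repeat_len_range[0] - 1, -1):
        positions: dict[str, list[int]] = {}
        for i in range(n - rl + 1):
            positions.setdefault(genome[i : i + rl], []).append(i)
        for mer, pos in positions.items():
            if len(pos) < min_repeats:
                continue
            # chain successive occurrences with spacer-window gaps
            chain = [pos[0]]
            for p in pos[1:]:
                gap = p - chain[-1] - rl
                if spacer_len_range[0] <= gap <= spacer_len_range[1]:
                    chain.append(p)
                else:
                    if len(chain) >= min_repeats:
                        candidates.append((chain[0], list(chain), mer, rl))
                    chain = [p]
            if len(chain) >= min_repeats:
                candidates.append((chain[0], list(chain), mer, rl))

    accepted: list[CrisprArray] = []
    covered: list[tuple[int, int]] = []  # 0-based [start, end) spans
    candidates.sort(key=lambda c: (-len(c[1]), -c[3], c[0]))
    for start, chain, mer, rl in candidates:
        end = chain[-1] + rl
        if any(s < end and start < e for s, e in covered):
            continue
        spacers = tuple(
            genome[chain[i] + rl : chain[i + 1]] for i in range(len(chain) - 1)
        )
        accepted.append(
            CrisprArray(
                contig_id=contig_id,
                start=start + 1,
                repeat=mer,
                spacers=spacers,
            )
        )
        covered.append((start, end))
    accepted.sort(key=lambda a: a.start)
    return accepted


def _hamming_scan(
    contig_arr: np.ndarray, spacer: str, max_mismatches: int
) -> list[tuple[int, int]]:
    """All (0-based position, mismatches) of full-length Hamming matches."""
    m = len(spacer)
    if m > len(contig_arr):
        return []
    spacer_arr = np.frombuffer(spacer.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(contig_arr, m)
    mismatches = (windows != spacer_arr).sum(axis=1)
    hits = np.nonzero(mismatches <= max_mismatches)[0]
    return [(int(i), int(mismatches[i])) for i in hits]


def match_spacers(
    spacers: dict[str, str],
    contigs: dict[str, str],
    max_mismatches: int = 2,
    search_both_strands: bool = True,
) -> list[SpacerMatch]:
    """Find every full-coverage spacer occurrence on the phage contigs.

    A hit requires the whole spacer to align (no indels) with at most
    ``max_mismatches`` substitutions; overlapping hits are all reported.
    Reverse-complement occurrences are reported with strand '-' at the
    forward-strand position of the alignment start.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be nonnegative")
    matches: list[SpacerMatch] = []
    for contig_id in sorted(contigs):
        seq = contigs[contig_id].upper()
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for spacer_id in sorted(spacers):
            spacer = spacers[spacer_id].upper()
            for pos, mm in _hamming_scan(arr, spacer, max_mismatches):
                matches.append(
                    SpacerMatch(spacer_id, contig_id, pos + 1, "+", mm)
                )
            if search_both_strands:
                rc = reverse_complement(spacer)
                if rc != spacer:
                    for pos, mm in _hamming_scan(arr, rc, max_mismatches):
                        matches.append(
                            SpacerMatch(spacer_id, contig_id, pos + 1, "-", mm)
                        )
    return matches
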