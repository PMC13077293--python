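"""In-silico PCR: primer placement under a 3'-anchored mismatch policy.

The matching model is ungapped substitution-only comparison of a primer
against every placement on a template.  Two rules govern an amplification
call:

* a *mismatch budget* caps the number of primer-template mismatches
  tolerated outside the anchor (0-2 in typical coverage evaluations), and
* a *3' anchor* of ``anchor_len`` terminal primer positions must match
  exactly — a mismatch under the anchor disqualifies the site regardless of
  budget, modelling the disproportionate effect of 3'-terminal mismatches
  on polymerase extension.

Primer and template IUPAC codes are compared set-wise: in the default
``intersection`` mode a position matches when the two codes share at least
one concrete base (primer R vs template N matches); ``strict`` mode
requires the template base to be concrete and contained in the primer's
set.

Matching is vectorized over all placements with a 4-bit base encoding
(A=1, C=2, G=4, T=8): codes are compatible iff their bit patterns
intersect.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .seqcore import IUPAC_BITS, Primer, SeqRecord, reverse_complement

_CONCRETE_BITS = frozenset((1, 2, 4, 8))

_ENCODE = np.zeros(128, dtype=np.uint8)
for _code, _bits in IUPAC_BITS.items():
    _ENCODE[ord(_code)] = _bits


def encode(seq: str) -> np.ndarray:
    """Encode an IUPAC string as a uint8 bit-pattern array."""
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 0).any():
        bad = int(np.argmax(arr == 0))
        raise ValueError(f"invalid IUPAC code {seq[bad]!r} at position {bad + 1}")
    return arr


@dataclass(frozen=True)
class MatchPolicy:
    """Parameters of the amplification-call predicate.

    mismatch_budget : tolerated mismatches outside the anchor (>= 0).
    anchor_len : number of 3'-terminal primer positions that must match
        exactly (2 by default).
    template_ambiguity : "intersection" (permissive; default) or "strict".
    scan_strand : "sense_only" (oriented references; default) or "both".
    max_amplicon_len : cap on predicted amplicon length in pair mode.
    """

    mismatch_budget: int = 2
    anchor_len: int = 2
    template_ambiguity: str = "intersection"
    scan_strand: str = "sense_only"
    max_amplicon_len: int = 2000

    def __post_init__(self) -> None:
        if self.mismatch_budget < 0:
            raise ValueError("mismatch_budget must be >= 0")
        if self.anchor_len < 0:
            raise ValueError("anchor_len must be >= 0")
        if self.template_ambiguity not in ("intersection", "strict"):
            raise ValueError(f"unknown template_ambiguity {self.template_ambiguity!r}")
        if self.scan_strand not in ("sense_only", "both"):
            raise ValueError(f"unknown scan_strand {self.scan_strand!r}")
        if self.max_amplicon_len < 1:
            raise ValueError("max_amplicon_len must be >= 1")


@dataclass(frozen=True)
class BindingSite:
    """Best placement of a primer on a template.

    Coordinates are 0-based half-open on the sense strand; ``strand`` is
    "+" when the primer anneals to the antisense strand and extends
    rightward (forward primers), "-" when it anneals to the sense strand
    (reverse primers, or forward primers hit on the opposite strand).
    ``mismatch_mask`` is in primer 5'->3' order; ``mismatch_count`` counts
    mismatches outside the final ``anchor_len`` positions.
    """

    template_id: str
    start: int
    end: int
    strand: str
    mismatch_count: int
    anchor_ok: bool
    mismatch_mask: tuple[bool, ...]

    @property
    def mask_string(self) -> str:
        """Dot/X rendering of the mask, primer 5'->3' (e.g. ``....X..``)."""
        return "".join("X" if m else "." for m in self.mismatch_mask)

    def qualifies(self, budget: int) -> bool:
        return self.anchor_ok and self.mismatch_count <= budget


@dataclass(frozen=True)
class AmplificationCall:
    """Single-primer amplification verdict for one template."""

    template_id: str
    primer_name: str
    amplified: bool
    best_site: BindingSite | None
    policy: MatchPolicy


@dataclass(frozen=True)
class Amplicon:
    """Predicted product of a forward/reverse primer pair on one template."""

    template_id: str
    forward_site: BindingSite
    reverse_site: BindingSite
    start: int          # outer span, 0-based half-open on the sense strand
    end: int
    insert_start: int   # between the two primer footprints
    insert_end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def insert_length(self) -> int:
        return self.insert_end - self.insert_start


def window_mismatches(
    primer: Primer, template_window: str, policy: MatchPolicy
) -> tuple[tuple[bool, ...], int, bool]:
    """Compare a primer to one template window of equal length.

    Returns ``(mismatch_mask, non_anchor_count, anchor_ok)`` with the mask
    in primer 5'->3' order.
    """
    if len(template_window) != len(primer):
        raise ValueError(
            f"window length {len(template_window)} != primer length {len(primer)}"
        )
    p = encode(primer.sequence)
    t = encode(template_window)
    mask = _mismatch_matrix(p, t[None, :], policy.template_ambiguity)[0]
    return _summarize(mask, min(policy.anchor_len, len(primer)))


def _mismatch_matrix(p: np.ndarray, windows: np.ndarray, mode: str) -> np.ndarray:
    """Boolean mismatch matrix, one row per window, primer 5'->3' columns."""
    inter = (windows & p) == 0
    if mode == "strict":
        concrete = np.isin(windows, (1, 2, 4, 8))
        return inter | ~concrete
    return inter


def _summarize(mask: np.ndarray, anchor_len: int) -> tuple[tuple[bool, ...], int, bool]:
    if anchor_len:
        non_anchor = int(mask[:-anchor_len].sum()) if anchor_len < len(mask) else 0
        anchor_ok = not mask[len(mask) - anchor_len:].any()
    else:
        non_anchor = int(mask.sum())
        anchor_ok = True
    return tuple(bool(b) for b in mask), non_anchor, anchor_ok


def _scan_oriented(
    p_bits: np.ndarray, t_bits: np.ndarray, anchor_len: int, mode: str,
    flip_mask: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """Evaluate every placement; returns (masks, non_anchor_counts, anchor_ok).

    ``flip_mask`` reverses window columns into primer 5'->3' order (used
    when the primer footprint is the reverse complement on the sense
    strand, so the primer's 3' anchor sits at the leftmost columns).
    """
    k, n = len(p_bits), len(t_bits)
    if k > n:
        return None
    windows = np.lib.stride_tricks.sliding_window_view(t_bits, k)
    masks = _mismatch_matrix(p_bits, windows, mode)
    if flip_mask:
        masks = masks[:, ::-1]
    anchor_len = min(anchor_len, k)
    if anchor_len:
        non_anchor = masks[:, : k - anchor_len].sum(axis=1)
        anchor_ok = ~masks[:, k - anchor_len:].any(axis=1)
    else:
        non_anchor = masks.sum(axis=1)
        anchor_ok = np.ones(len(masks), dtype=bool)
    return masks, non_anchor.astype(np.int64), anchor_ok


def _best_index(non_anchor: np.ndarray, anchor_ok: np.ndarray, budget: int) -> tuple[int, bool]:
    """Best placement index under (qualifying first, min count, leftmost)."""
    qual = anchor_ok & (non_anchor <= budget)
    if qual.any():
        counts = np.where(qual, non_anchor, np.iinfo(np.int64).max)
        return int(np.argmin(counts)), True
    return int(np.argmin(non_anchor)), False


def scan_template(
    primer: Primer, record: SeqRecord, policy: MatchPolicy
) -> BindingSite | None:
    """Best binding site of a primer on a template, or None.

    Every ungapped placement is evaluated.  Forward primers scan the sense
    strand (footprint equals the primer sequence); reverse primers scan
    their reverse-complement footprint on the sense strand.  With
    ``scan_strand="both"`` the opposite orientation is also scanned and the
    better site returned (ties prefer the primary orientation).

    Among placements that satisfy the anchor and the budget the site with
    the fewest non-anchor mismatches wins, leftmost on ties; when no
    placement qualifies, the overall minimal-mismatch placement is returned
    (its ``qualifies`` method reports False) so reports can show how close
    the primer came.  Returns None when the primer is longer than the
    template.
    """
    t_bits = encode(record.sequence)
    k = len(primer)
    if k > len(t_bits):
        return None
    mode = policy.template_ambiguity
    anchor = policy.anchor_len
    budget = policy.mismatch_budget

    # Primary orientation: "+" for forward primers (footprint = primer),
    # "-" for reverse primers (footprint = revcomp(primer), anchor leftmost).
    orientations: list[tuple[str, np.ndarray, bool]] = []
    if primer.role == "forward":
        orientations.append(("+", encode(primer.sequence), False))
        if policy.scan_strand == "both":
            orientations.append(("-", encode(reverse_complement(primer.sequence)), True))
    else:
        orientations.append(("-", encode(reverse_complement(primer.sequence)), True))
        if policy.scan_strand == "both":
            orientations.append(("+", encode(primer.sequence), False))

    best: BindingSite | None = None
    best_key: tuple | None = None
    for rank, (strand, p_bits, flip) in enumerate(orientations):
        scanned = _scan_oriented(p_bits, t_bits, anchor, mode, flip)
        if scanned is None:
            continue
        masks, non_anchor, anchor_ok = scanned
        idx, qualified = _best_index(non_anchor, anchor_ok, budget)
        site = BindingSite(
            template_id=record.id,
            start=idx,
            end=idx + k,
            strand=strand,
            mismatch_count=int(non_anchor[idx]),
            anchor_ok=bool(anchor_ok[idx]),
            mismatch_mask=tuple(bool(b) for b in masks[idx]),
        )
        key = (not qualified, site.mismatch_count, rank, site.start)
        if best_key is None or key < best_key:
            best, best_key = site, key
    return best


def call_single(
    primer: Primer, record: SeqRecord, policy: MatchPolicy
) -> AmplificationCall:
    """Would this primer alone prime this template under the policy?"""
    site = scan_template(primer, record, policy)
    amplified = site is not None and site.qualifies(policy.mismatch_budget)
    return AmplificationCall(
        template_id=record.id,
        primer_name=primer.name,
        amplified=amplified,
        best_site=site,
        policy=policy,
    )


def call_pair(
    forward: Primer, reverse: Primer, record: SeqRecord, policy: MatchPolicy
) -> Amplicon | None:
    """Predict the amplicon of a primer pair on a template, or None.

    The forward site is the best qualifying sense-strand site; the reverse
    primer is then scanned as its reverse-complement footprint downstream
    of the forward footprint, with the anchor rule applied to the reverse
    primer's own 3' end (which faces the insert).  The shortest qualifying
    amplicon within ``max_amplicon_len`` is returned.
    """
    if forward.role != "forward":
        raise ValueError(f"primer {forward.name!r} is not a forward primer")
    if reverse.role != "reverse":
        raise ValueError(f"primer {reverse.name!r} is not a reverse primer")
    fwd_site = scan_template(forward, record, policy)
    if fwd_site is None or not fwd_site.qualifies(policy.mismatch_budget):
        return None

    t_bits = encode(record.sequence)
    rc_bits = encode(reverse_complement(reverse.sequence))
    k = len(reverse)
    downstream = t_bits[fwd_site.end:]
    scanned = _scan_oriented(rc_bits, downstream, policy.anchor_len,
                             policy.template_ambiguity, flip_mask=True)
    if scanned is None:
        return None
    masks, non_anchor, anchor_ok = scanned
    qual = anchor_ok & (non_anchor <= policy.mismatch_budget)
    if not qual.any():
        return None
    offset = int(np.argmax(qual))  # nearest downstream => shortest amplicon
    rev_start = fwd_site.end + offset
    amp_len = rev_start + k - fwd_site.start
    if amp_len > policy.max_amplicon_len:
        return None
    rev_site = BindingSite(
        template_id=record.id,
        start=rev_start,
        end=rev_start + k,
        strand="-",
        mismatch_count=int(non_anchor[offset]),
        anchor_ok=bool(anchor_ok[offset]),
        mismatch_mask=tuple(bool(b) for b in masks[offset]),
    )
    return Amplicon(
        template_id=record.id,
        forward_site=fwd_site,
        reverse_site=rev_site,
        start=fwd_site.start,
        end=rev_site.end,
        insert_start=fwd_site.end,
        insert_end=rev_site.start,
    )


def extract_insert(
    amplicon: Amplicon, record: SeqRecord, include_primers: bool = False
) -> str:
    """Template substring between the primer footprints (or the outer span)."""
    if include_primers:
        return record.sequence[amplicon.start:amplicon.end]
    return record.sequence[amplicon.insert_start:amplicon.insert_end]


def min_mismatch_counts(primer: Primer, record: SeqRecord, policy: MatchPolicy) -> int | None:
    """Minimum anchor-respecting mismatch count over qualifying-anchor sites.

    Helper for coverage: returns the smallest non-anchor mismatch count
    among placements with an intact anchor, or None when no placement has
    an intact anchor (or the primer does not fit).  A template amplifies at
    budget b iff this value is <= b, so one scan serves every budget.
    """
    t_bits = encode(record.sequence)
    k = len(primer)
    if k > len(t_bits):
        return None
    best: int | None = None
    orientations: list[tuple[np.ndarray, bool]] = []
    if primer.role == "forward":
        orientations.append((encode(primer.sequence), False))
        if policy.scan_strand == "both":
            orientations.append((encode(reverse_complement(primer.sequence)), True))
    else:
        orientations.append((encode(reverse_complement(primer.sequence)), True))
        if policy.scan_strand == "both":
            orientations.append((encode(primer.sequence), False))
    for p_bits, flip in orientations:
        scanned = _scan_oriented(p_bits, t_bits, policy.anchor_len,
                                 policy.template_ambiguity, flip)
        if scanned is None:
            continue
        _, non_anchor, anchor_ok = scanned
        if anchor_ok.any():
            m = int(non_anchor[anchor_ok].min())
            best = m if best is None else min(best, m)
    return best
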