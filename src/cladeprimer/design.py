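"""Host-exclusion primer design over a conserved anchor region.

The procedure generalizes the forward-primer shift that turns a universal
fungal primer into a host-excluding one: slide candidate windows along a
target consensus, score each candidate's mismatches to every host at its
homologous site — weighting the 3'-terminal window, where mismatches
disproportionately block extension — and rank candidates by host
exclusion first, target coverage second.

A candidate qualifies when (a) every host carries at least
``min_terminal_mismatches`` mismatches within the candidate's final
``terminal_window`` positions, (b) at least one of them sits under the
final two bases (when required), and (c) primer QC bounds (GC, melting
temperature, homopolymer run, degeneracy) pass.  Ranking is a lexicographic
order, not a weighted sum, so the ordering is reproducible and explainable:

1. minimum over hosts of final-2 mismatches, descending;
2. minimum over hosts of terminal-window mismatches, descending;
3. target coverage at budget 0, descending;
4. degeneracy, ascending;
5. leftmost window.

Host sites are located by best-mismatch placement, so unaligned host FASTA
works; no fixed alignment column is assumed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.SeqUtils import MeltingTemp as _mt

from .coverage import coverage_table
from .insilico import MatchPolicy, _mismatch_matrix, encode
from .seqcore import (
    GAP_CHARS,
    IUPAC_BITS,
    Primer,
    SeqRecord,
    base_set,
    degeneracy as seq_degeneracy,
    expansions,
)

_BITS_TO_CODE = {bits: code for code, bits in IUPAC_BITS.items()}
_BASES = "ACGT"


@dataclass(frozen=True)
class DesignParams:
    """Tunable knobs of the designer.

    ``terminal_window`` (default 4) is the 3'-terminal span scored for host
    mismatches — the span a four-base 3'-ward shift of a universal primer
    brings over host-variable positions.  ``min_terminal_mismatches``
    (default 2) is the exclusion floor every host must meet.  Consensus
    columns collapse to the majority base at frequency >= ``consensus_threshold``
    (default 0.9), otherwise to the minimal IUPAC code covering bases at
    frequency >= ``minor_freq`` (default 0.05).  QC bounds are advisory:
    failing candidates are reported, flagged unqualified.
    """

    min_len: int = 17
    max_len: int = 22
    terminal_window: int = 4
    min_terminal_mismatches: int = 2
    require_final2: bool = True
    consensus_threshold: float = 0.9
    minor_freq: float = 0.05
    max_degeneracy: int = 4
    gc_min: float = 0.30
    gc_max: float = 0.70
    tm_min: float = 50.0
    tm_max: float = 65.0
    max_homopolymer: int = 4
    tm_method: str = "nn"     # "nn" (nearest-neighbor) or "wallace" (2+4 rule)

    def __post_init__(self) -> None:
        if not 10 <= self.min_len <= self.max_len <= 40:
            raise ValueError("primer length range must sit within [10, 40]")
        if not 0 < self.consensus_threshold <= 1:
            raise ValueError("consensus_threshold must be in (0, 1]")
        if self.terminal_window > self.min_len:
            raise ValueError("terminal_window cannot exceed min primer length")
        if self.tm_method not in ("nn", "wallace"):
            raise ValueError(f"unknown tm_method {self.tm_method!r}")


@dataclass(frozen=True)
class QCMetrics:
    length: int
    gc_fraction: float
    tm: float
    max_homopolymer: int
    degeneracy: int


@dataclass(frozen=True)
class HostProfile:
    """Mismatch profile of a candidate against one host's best site."""

    host_id: str
    site_start: int
    total_mismatches: int
    terminal_window_mm: int
    final2_mm: int
    site_seq: str


@dataclass(frozen=True)
class CandidatePrimer:
    """A scored design-window candidate."""

    start: int
    end: int
    sequence: str
    coverage: dict[int, float]          # budget -> percent of targets
    host_profiles: tuple[HostProfile, ...]
    qc: QCMetrics
    qualified: bool
    fail_reasons: tuple[str, ...] = ()
    rank: int | None = None

    @property
    def min_host_final2(self) -> int:
        return min(p.final2_mm for p in self.host_profiles)

    @property
    def max_host_terminal(self) -> int:
        return max(p.terminal_window_mm for p in self.host_profiles)

    @property
    def min_host_terminal(self) -> int:
        return min(p.terminal_window_mm for p in self.host_profiles)


@dataclass(frozen=True)
class Consensus:
    """Consensus string with a map back to alignment columns."""

    sequence: str
    column_map: tuple[int, ...]   # consensus position -> alignment column

    def __len__(self) -> int:
        return len(self.sequence)


def build_consensus(
    aligned_targets: Sequence[SeqRecord | str],
    threshold: float = 0.9,
    minor_freq: float = 0.05,
) -> Consensus:
    """Collapse an alignment column-wise into a (possibly degenerate) consensus.

    Ambiguous template codes contribute fractionally to each base they
    denote.  Columns where gaps hold the majority are dropped; the column
    map records each consensus position's original alignment column.
    """
    seqs = [s.sequence if isinstance(s, SeqRecord) else s for s in aligned_targets]
    if not seqs:
        raise ValueError("no sequences given")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("ragged alignment: sequences differ in length")
    out: list[str] = []
    col_map: list[int] = []
    for col in range(length):
        counts = dict.fromkeys(_BASES, 0.0)
        gaps = 0
        for s in seqs:
            ch = s[col]
            if ch in GAP_CHARS:
                gaps += 1
                continue
            bs = base_set(ch)
            for b in bs:
                counts[b] += 1.0 / len(bs)
        n_bases = len(seqs) - gaps
        if gaps * 2 > len(seqs) or n_bases == 0:
            continue  # gap-majority column dropped
        freqs = {b: c / n_bases for b, c in counts.items()}
        top = max(_BASES, key=lambda b: (freqs[b], b))
        if freqs[top] >= threshold:
            code = top
        else:
            keep = [b for b in _BASES if freqs[b] >= minor_freq] or [top]
            code = _BITS_TO_CODE[sum(IUPAC_BITS[b] for b in keep)]
        out.append(code)
        col_map.append(col)
    return Consensus(sequence="".join(out), column_map=tuple(col_map))


def enumerate_windows(
    consensus: Consensus | str, params: DesignParams | None = None
) -> list[tuple[int, str]]:
    """All (start, sequence) windows within the length range and degeneracy cap."""
    if params is None:
        params = DesignParams()
    seq = consensus.sequence if isinstance(consensus, Consensus) else consensus
    out: list[tuple[int, str]] = []
    for length in range(params.min_len, params.max_len + 1):
        for start in range(0, len(seq) - length + 1):
            window = seq[start:start + length]
            if seq_degeneracy(window) <= params.max_degeneracy:
                out.append((start, window))
    return out


def qc_metrics(seq: str, params: DesignParams | None = None) -> QCMetrics:
    """Standard primer QC: GC, melting temperature, homopolymer run, degeneracy.

    GC counts degenerate codes fractionally by set composition.  Tm uses a
    nearest-neighbor thermodynamic estimate at standard salt by default
    (averaged over concrete expansions for degenerate sequences), or the
    simple 2+4-degree rule.  Homopolymer runs are measured over concrete
    bases only.
    """
    if params is None:
        params = DesignParams()
    gc = sum(len(base_set(ch) & {"G", "C"}) / len(base_set(ch)) for ch in seq) / len(seq)
    run = best = 1
    for a, b in zip(seq, seq[1:]):
        if a == b and a in _BASES:
            run += 1
            best = max(best, run)
        else:
            run = 1
    deg = seq_degeneracy(seq)
    if params.tm_method == "wallace":
        at = len(seq) - gc * len(seq)
        tm = 2.0 * at + 4.0 * gc * len(seq)
    else:
        if deg <= 64:
            tms = [float(_mt.Tm_NN(e)) for e in expansions(seq)]
            tm = float(np.mean(tms))
        else:  # highly degenerate: fall back to the 2+4 rule
            at = len(seq) - gc * len(seq)
            tm = 2.0 * at + 4.0 * gc * len(seq)
    return QCMetrics(
        length=len(seq), gc_fraction=gc, tm=tm,
        max_homopolymer=best, degeneracy=deg,
    )


def score_candidate(
    candidate: tuple[int, str],
    targets: Sequence[SeqRecord],
    hosts: Sequence[SeqRecord],
    policy: MatchPolicy | None = None,
    params: DesignParams | None = None,
) -> CandidatePrimer:
    """Score one window: target coverage, per-host 3'-mismatch profile, QC."""
    if params is None:
        params = DesignParams()
    if policy is None:
        policy = MatchPolicy()
    if not targets or not hosts:
        raise ValueError("targets and hosts must be non-empty")
    start, seq = candidate
    primer = Primer(f"cand_{start}_{len(seq)}", seq, "forward")
    table = coverage_table([primer], targets, [0, 1, 2], policy)
    cov = {b: table.percent(primer.name, b) for b in (0, 1, 2)}

    w = params.terminal_window
    p_bits = encode(seq)
    profiles: list[HostProfile] = []
    for host in hosts:
        t = encode(host.sequence)
        windows = np.lib.stride_tricks.sliding_window_view(t, len(seq))
        masks = _mismatch_matrix(p_bits, windows, policy.template_ambiguity)
        totals = masks.sum(axis=1)
        idx = int(np.argmin(totals))
        mask = masks[idx]
        profiles.append(
            HostProfile(
                host_id=host.id,
                site_start=idx,
                total_mismatches=int(totals[idx]),
                terminal_window_mm=int(mask[-w:].sum()),
                final2_mm=int(mask[-2:].sum()),
                site_seq=host.sequence[idx:idx + len(seq)],
            )
        )

    qc = qc_metrics(seq, params)
    reasons: list[str] = []
    if min(p.terminal_window_mm for p in profiles) < params.min_terminal_mismatches:
        reasons.append("host_terminal_mismatches")
    if params.require_final2 and min(p.final2_mm for p in profiles) < 1:
        reasons.append("host_final2")
    if not params.gc_min <= qc.gc_fraction <= params.gc_max:
        reasons.append("gc")
    if not params.tm_min <= qc.tm <= params.tm_max:
        reasons.append("tm")
    if qc.max_homopolymer > params.max_homopolymer:
        reasons.append("homopolymer")
    if qc.degeneracy > params.max_degeneracy:
        reasons.append("degeneracy")
    return CandidatePrimer(
        start=start, end=start + len(seq), sequence=seq,
        coverage=cov, host_profiles=tuple(profiles), qc=qc,
        qualified=not reasons, fail_reasons=tuple(reasons),
    )


def _rank_key(c: CandidatePrimer) -> tuple:
    return (
        -c.min_host_final2,
        -c.min_host_terminal,
        -c.coverage[0],
        c.qc.degeneracy,
        c.start,
    )


def rank_candidates(
    candidates: Sequence[CandidatePrimer],
    params: DesignParams | None = None,
) -> list[CandidatePrimer]:
    """Order candidates: qualified first under the lexicographic rule, then
    unqualified under the same key, all with 1-based ranks assigned."""
    qualified = sorted((c for c in candidates if c.qualified), key=_rank_key)
    rest = sorted((c for c in candidates if not c.qualified), key=_rank_key)
    out: list[CandidatePrimer] = []
    for i, c in enumerate(itertools.chain(qualified, rest), start=1):
        out.append(
            CandidatePrimer(
                start=c.start, end=c.end, sequence=c.sequence,
                coverage=c.coverage, host_profiles=c.host_profiles,
                qc=c.qc, qualified=c.qualified,
                fail_reasons=c.fail_reasons, rank=i,
            )
        )
    return out


def design_primers(
    aligned_targets: Sequence[SeqRecord],
    hosts: Sequence[SeqRecord],
    params: DesignParams | None = None,
    policy: MatchPolicy | None = None,
    unaligned_targets: Sequence[SeqRecord] | None = None,
) -> list[CandidatePrimer]:
    """Full design pass: consensus -> windows -> scoring -> ranking.

    ``aligned_targets`` build the consensus; coverage is evaluated against
    ``unaligned_targets`` when given (e.g. a larger unaligned reference
    set), else against the gap-stripped aligned targets themselves.
    """
    if params is None:
        params = DesignParams()
    consensus = build_consensus(
        aligned_targets, params.consensus_threshold, params.minor_freq
    )
    windows = enumerate_windows(consensus, params)
    cov_targets = list(unaligned_targets) if unaligned_targets is not None else [
        SeqRecord(id=r.id, sequence=r.sequence.replace("-", "").replace(".", ""),
                  lineage=r.lineage, origin=r.origin)
        for r in aligned_targets
    ]
    scored = [
        score_candidate(w, cov_targets, hosts, policy, params) for w in windows
    ]
    return rank_candidates(scored, params)


def alignment_snippet(candidate: CandidatePrimer, width: int = 0) -> str:
    """Human-readable primer-over-host alignment with mismatches marked.

    The candidate is printed once, then each host's best site with ``*``
    under every mismatched position — the conventional way to show designed
    3' mismatches against host templates.
    """
    lines = [f"candidate  5'-{candidate.sequence}-3'  "
             f"(window {candidate.start + 1}..{candidate.end}, 1-based)"]
    for prof in candidate.host_profiles:
        marks = "".join(
            "*" if not (base_set(a) & base_set(b)) else " "
            for a, b in zip(candidate.sequence, prof.site_seq)
        )
        lines.append(f"{prof.host_id:<10}    {prof.site_seq}")
        lines.append(f"{'':<10}    {marks}   "
                     f"({prof.terminal_window_mm} mm in 3' window, "
                     f"{prof.final2_mm} in final 2)")
    return "\n".join(lines)
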