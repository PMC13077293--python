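"""Seeded synthetic reference sets with planted primer sites.

Every generator here is a pure function of its spec and seed (numpy
``default_rng``; no global RNG state), so fixtures are byte-identical
across runs and platforms.  Three kinds of sets are produced:

* *targets* — amplifiable references built as flank + forward-primer site
  + insert + reverse-primer complement site + flank, with a controlled
  per-record mismatch spectrum at the forward site (exact, one non-anchor
  mismatch, or a 3'-anchor mismatch);
* *hosts* — references homologous to the targets at the priming locus but
  carrying 2-4 substitutions within the primer's 3'-terminal window, at
  least one of them under the final two bases.  This is the mismatch
  pattern a host-excluding primer is designed to exploit: such sites fail
  the anchor rule at every budget;
* *mock* — a defined community of species-labelled records with exact
  sites for all primers of interest, the synthetic analogue of a mock
  community positive control.

Generated records are verified post hoc with the matching engine: the
realized mismatch profile must equal the planted one, and flanks/inserts
are rejection-sampled so they contain no accidental qualifying site.
Insert lengths default to 150-450 nt (ITS2-like).

``simulate_library`` is a deliberately all-or-nothing idealization of
amplification competition: templates either amplify (and draw reads in
proportion to copy number) or yield nothing.  It carries no efficiency
model and is a qualitative tool only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .insilico import MatchPolicy, call_pair, min_mismatch_counts, scan_template, window_mismatches
from .seqcore import (
    ITS3,
    ITS3_CORALF,
    ITS4,
    Lineage,
    Primer,
    SeqRecord,
    base_set,
    reverse_complement,
)

_BASES = "ACGT"
_MAX_REDRAWS = 200


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic target/host reference set.

    ``spectrum`` gives the number of target records whose forward-primer
    site carries, respectively, 0 mismatches, 1 non-anchor mismatch, and
    >=1 anchor (3'-terminal) mismatch; the counts must sum to
    ``n_targets``.  Hosts carry ``host_terminal_mm_range`` substitutions
    within the final ``host_terminal_window`` primer positions, with at
    least one inside the final two when ``host_require_final2`` is set.
    """

    n_targets: int = 10
    spectrum: tuple[int, int, int] = (7, 2, 1)
    taxonomy_plan: tuple[tuple[str, int], ...] | None = None
    insert_len_range: tuple[int, int] = (150, 450)
    flank_len_range: tuple[int, int] = (20, 60)
    n_hosts: int = 3
    host_terminal_window: int = 4
    host_terminal_mm_range: tuple[int, int] = (2, 4)
    host_require_final2: bool = True
    anchor_len: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_targets < 1:
            raise ValueError("n_targets must be >= 1")
        if sum(self.spectrum) != self.n_targets:
            raise ValueError(
                f"mismatch spectrum {self.spectrum} does not sum to "
                f"n_targets={self.n_targets}"
            )
        if self.taxonomy_plan is not None:
            tot = sum(n for _, n in self.taxonomy_plan)
            if tot != self.n_targets:
                raise ValueError(
                    f"taxonomy plan counts sum to {tot}, expected {self.n_targets}"
                )
        lo, hi = self.host_terminal_mm_range
        if not 1 <= lo <= hi <= self.host_terminal_window:
            raise ValueError(
                f"host terminal mismatch range {self.host_terminal_mm_range} "
                f"does not fit window {self.host_terminal_window}"
            )
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass(frozen=True)
class RecordTruth:
    """Planted ground truth for one generated record."""

    slot: str                 # exact | non_anchor | anchor | host | mock
    site_start: int           # forward-primer footprint, 0-based
    site_seq: str
    non_anchor_mm: int
    anchor_mm: int
    terminal_window_mm: int = 0
    final2_mm: int = 0
    insert_len: int = 0


@dataclass(frozen=True)
class Fixture:
    """A generated record set plus its per-record ground truth manifest."""

    records: tuple[SeqRecord, ...]
    truth: dict[str, RecordTruth] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _realize(rng: np.random.Generator, seq: str) -> str:
    """One concrete realization of a degenerate sequence."""
    out = []
    for ch in seq:
        opts = sorted(base_set(ch))
        out.append(opts[rng.integers(0, len(opts))] if len(opts) > 1 else opts[0])
    return "".join(out)


def _mutate_against(rng: np.random.Generator, primer_seq: str, site: list[str],
                    pos: int) -> None:
    """Substitute site[pos] with a base outside the primer's set there."""
    options = [b for b in _BASES if b not in base_set(primer_seq[pos])]
    site[pos] = options[rng.integers(0, len(options))]


def _default_taxonomy(spec: FixtureSpec) -> list[Lineage]:
    if spec.taxonomy_plan is None:
        half = (spec.n_targets + 1) // 2
        plan = (("Ascomycota", half), ("Basidiomycota", spec.n_targets - half))
    else:
        plan = spec.taxonomy_plan
    lineages: list[Lineage] = []
    for phylum, n in plan:
        for _ in range(n):
            lineages.append(Lineage((("kingdom", "Fungi"), ("phylum", phylum))))
    return lineages


def _clean_segment(rng: np.random.Generator, n: int, primers: Sequence[Primer],
                   policy: MatchPolicy) -> str:
    """Random segment with no qualifying site for any primer (rejection sampled)."""
    for _ in range(_MAX_REDRAWS):
        seg = _random_seq(rng, n)
        ok = True
        for p in primers:
            if len(p) <= n:
                best = min_mismatch_counts(p, SeqRecord(id="tmp", sequence=seg), policy)
                if best is not None and best <= policy.mismatch_budget:
                    ok = False
                    break
        if ok:
            return seg
    raise RuntimeError("could not sample a primer-free segment")  # pragma: no cover


def make_target_set(
    spec: FixtureSpec,
    forward: Primer = ITS3_CORALF,
    reverse: Primer = ITS4,
) -> Fixture:
    """Generate amplifiable target records with a planted mismatch spectrum.

    The realized profile of every record is verified with the matching
    engine (best forward site at the planted offset with the planted
    mismatch counts); records failing verification are redrawn.
    """
    rng = np.random.default_rng(spec.seed)
    policy = MatchPolicy(mismatch_budget=2, anchor_len=spec.anchor_len)
    slots = (
        ["exact"] * spec.spectrum[0]
        + ["non_anchor"] * spec.spectrum[1]
        + ["anchor"] * spec.spectrum[2]
    )
    lineages = _default_taxonomy(spec)
    records: list[SeqRecord] = []
    truth: dict[str, RecordTruth] = {}
    both = (forward, reverse)
    for i, slot in enumerate(slots):
        for _ in range(_MAX_REDRAWS):
            site = list(_realize(rng, forward.sequence))
            non_anchor_mm = anchor_mm = 0
            k = len(site)
            if slot == "non_anchor":
                pos = int(rng.integers(0, k - spec.anchor_len))
                _mutate_against(rng, forward.sequence, site, pos)
                non_anchor_mm = 1
            elif slot == "anchor":
                pos = int(rng.integers(k - spec.anchor_len, k))
                _mutate_against(rng, forward.sequence, site, pos)
                anchor_mm = 1
            site_seq = "".join(site)
            flank5 = _clean_segment(rng, int(rng.integers(*spec.flank_len_range)), both, policy)
            insert = _clean_segment(rng, int(rng.integers(*spec.insert_len_range)), both, policy)
            flank3 = _clean_segment(rng, int(rng.integers(*spec.flank_len_range)), both, policy)
            rev_site = reverse_complement(_realize(rng, reverse.sequence))
            seq = flank5 + site_seq + insert + rev_site + flank3
            rec = SeqRecord(
                id=f"target_{i + 1:03d}", sequence=seq,
                lineage=lineages[i], origin="target",
            )
            if _verify_target(rec, forward, spec, slot, len(flank5)):
                records.append(rec)
                truth[rec.id] = RecordTruth(
                    slot=slot, site_start=len(flank5), site_seq=site_seq,
                    non_anchor_mm=non_anchor_mm, anchor_mm=anchor_mm,
                    insert_len=len(insert),
                )
                break
        else:  # pragma: no cover
            raise RuntimeError(f"could not generate target record {i}")
    return Fixture(records=tuple(records), truth=truth)


def _verify_target(rec: SeqRecord, forward: Primer, spec: FixtureSpec,
                   slot: str, site_start: int) -> bool:
    policy = MatchPolicy(mismatch_budget=2, anchor_len=spec.anchor_len)
    best = min_mismatch_counts(forward, rec, policy)
    if slot == "exact":
        if best != 0:
            return False
    elif slot == "non_anchor":
        if best != 1:
            return False
    else:  # anchor mismatch: must not amplify at any budget <= 2
        if best is not None and best <= 2:
            return False
        return True
    site = scan_template(forward, rec, policy)
    return site is not None and site.start == site_start


# Combined forward site realizing both fITS7 (R as A) and ITS86F exactly;
# real host rDNA matches these universal primers nearly perfectly.
_UNIVERSAL_SITE = "GTGAATCATCGAATCTTTGAA"


def make_host_set(
    spec: FixtureSpec,
    primer: Primer = ITS3_CORALF,
    reverse: Primer = ITS4,
    universal_site: str | None = _UNIVERSAL_SITE,
) -> Fixture:
    """Generate host records carrying the designed 3'-terminal mismatch pattern.

    Each host's site for the designed ``primer`` differs from it by k
    substitutions (k drawn from ``host_terminal_mm_range``) inside the
    final ``host_terminal_window`` positions, with at least one under the
    final two bases when ``host_require_final2`` — such sites fail the
    anchor rule at every budget.  With ``host_require_final2`` off the
    substitutions are placed *outside* the final two when k allows,
    producing "leaky" hosts that amplify once the budget reaches k.

    Hosts also carry an intact universal-primer site downstream (set
    ``universal_site=None`` to omit), mirroring real host references that
    universal fungal primers amplify while the designed primer excludes.
    """
    rng = np.random.default_rng(spec.seed + 1)
    policy = MatchPolicy(mismatch_budget=2, anchor_len=spec.anchor_len)
    w = spec.host_terminal_window
    k_lo, k_hi = spec.host_terminal_mm_range
    records: list[SeqRecord] = []
    truth: dict[str, RecordTruth] = {}
    both = (primer, reverse)
    for i in range(spec.n_hosts):
        for _ in range(_MAX_REDRAWS):
            site = list(_realize(rng, primer.sequence))
            n = len(site)
            k = int(rng.integers(k_lo, k_hi + 1))
            window_positions = list(range(n - w, n))
            final2 = [p for p in window_positions if p >= n - 2]
            if spec.host_require_final2:
                first = final2[int(rng.integers(0, len(final2)))]
                rest = [p for p in window_positions if p != first]
                chosen = [first] + (list(rng.choice(rest, size=k - 1, replace=False))
                                    if k > 1 else [])
            else:
                outside = [p for p in window_positions if p < n - 2]
                pool = outside if k <= len(outside) else window_positions
                chosen = list(rng.choice(pool, size=k, replace=False))
            for pos in chosen:
                _mutate_against(rng, primer.sequence, site, int(pos))
            site_seq = "".join(site)
            mask, _, _ = window_mismatches(
                primer, site_seq, MatchPolicy(anchor_len=spec.anchor_len)
            )
            terminal_mm = sum(mask[n - w:])
            final2_mm = sum(mask[n - 2:])
            flank5 = _clean_segment(rng, int(rng.integers(*spec.flank_len_range)), both, policy)
            spacer = _clean_segment(rng, 26, both, policy)
            insert = _clean_segment(rng, int(rng.integers(*spec.insert_len_range)), both, policy)
            flank3 = _clean_segment(rng, int(rng.integers(*spec.flank_len_range)), both, policy)
            rev_site = reverse_complement(_realize(rng, reverse.sequence))
            middle = (spacer + universal_site) if universal_site else ""
            seq = flank5 + site_seq + middle + insert + rev_site + flank3
            rec = SeqRecord(
                id=f"host_{i + 1:03d}", sequence=seq,
                lineage=Lineage((("kingdom", "Animalia"), ("phylum", "Cnidaria"),
                                 ("class", "Anthozoa"))),
                origin="host",
            )
            best = min_mismatch_counts(primer, rec, policy)
            # planted profile must be exactly what the engine sees
            if final2_mm > 0:
                ok = best is None or best > 2
            else:
                ok = best == terminal_mm
            if ok:
                records.append(rec)
                truth[rec.id] = RecordTruth(
                    slot="host", site_start=len(flank5), site_seq=site_seq,
                    non_anchor_mm=terminal_mm - final2_mm, anchor_mm=final2_mm,
                    terminal_window_mm=terminal_mm, final2_mm=final2_mm,
                    insert_len=len(insert),
                )
                break
        else:  # pragma: no cover
            raise RuntimeError(f"could not generate host record {i}")
    return Fixture(records=tuple(records), truth=truth)


def make_mock(n_species: int = 10, seed: int = 0,
              reverse: Primer = ITS4) -> Fixture:
    """A synthetic mock community: n species-labelled, fully amplifiable records.

    Each record carries exact binding sites for ITS3-CoralF and for the
    universal forward primers (one site realizes both fITS7 and ITS86F),
    plus the reverse-primer complement, so every primer of interest calls
    it amplified at budget 0.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = np.random.default_rng(seed)
    policy = MatchPolicy(mismatch_budget=2)
    screen = (ITS3_CORALF, Primer("universal-site", _UNIVERSAL_SITE, "forward"), reverse)
    records: list[SeqRecord] = []
    truth: dict[str, RecordTruth] = {}
    for i in range(n_species):
        spacer = _clean_segment(rng, 26, screen, policy)
        flank5 = _clean_segment(rng, int(rng.integers(20, 60)), screen, policy)
        insert = _clean_segment(rng, int(rng.integers(150, 450)), screen, policy)
        flank3 = _clean_segment(rng, int(rng.integers(20, 60)), screen, policy)
        coralf_site = ITS3_CORALF.sequence  # concrete already
        seq = (flank5 + coralf_site + spacer + _UNIVERSAL_SITE + insert
               + reverse_complement(_realize(rng, reverse.sequence)) + flank3)
        rec = SeqRecord(
            id=f"mock_{i + 1:02d}", sequence=seq,
            lineage=Lineage((("kingdom", "Fungi"),
                             ("species", f"Mock_species_{i + 1}"))),
            origin="mock",
        )
        records.append(rec)
        truth[rec.id] = RecordTruth(
            slot="mock", site_start=len(flank5), site_seq=coralf_site,
            non_anchor_mm=0, anchor_mm=0, insert_len=len(insert),
        )
    return Fixture(records=tuple(records), truth=truth)


@dataclass(frozen=True)
class LibrarySimResult:
    """Outcome of the all-or-nothing amplification-competition simulator."""

    counts_by_origin: dict[str, int]
    fractions_by_origin: dict[str, float] | None   # None when nothing amplified
    depth: int
    n_amplifiable: int
    seed: int


def simulate_library(
    pool: Sequence[tuple[SeqRecord, float]],
    forward: Primer,
    reverse: Primer,
    policy: MatchPolicy,
    depth: int,
    seed: int,
) -> LibrarySimResult:
    """Draw sequencing reads multinomially over amplifiable pool templates.

    Templates whose pair call fails get zero reads; amplifiable templates
    draw reads in proportion to copy number.  When nothing amplifies the
    result carries all-zero counts and ``fractions_by_origin=None``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if any(c < 0 for _, c in pool):
        raise ValueError("copy numbers must be >= 0")
    rng = np.random.default_rng(seed)
    weights = []
    for rec, copies in pool:
        amp = call_pair(forward, reverse, rec, policy)
        weights.append(copies if amp is not None else 0.0)
    total = float(sum(weights))
    origins = [rec.origin or "unknown" for rec, _ in pool]
    counts_by_origin: dict[str, int] = {o: 0 for o in origins}
    if total == 0.0:
        return LibrarySimResult(
            counts_by_origin=counts_by_origin, fractions_by_origin=None,
            depth=depth, n_amplifiable=0, seed=seed,
        )
    probs = np.asarray(weights) / total
    draws = rng.multinomial(depth, probs)
    for origin, n in zip(origins, draws):
        counts_by_origin[origin] += int(n)
    fractions = {o: c / depth for o, c in counts_by_origin.items()}
    return LibrarySimResult(
        counts_by_origin=counts_by_origin,
        fractions_by_origin=fractions,
        depth=depth,
        n_amplifiable=int(sum(1 for w in weights if w > 0)),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Planted-discriminator fixture for the design module.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignFixture:
    """Aligned targets + hosts with a planted discriminative primer window.

    The target consensus region embeds a universal-style window (hosts
    match it exactly) and, four positions 3'-ward of its terminus, a
    shifted window whose final bases overlie host-variable positions: the
    layout a host-excluding primer shift exploits.
    """

    targets: tuple[SeqRecord, ...]
    hosts: tuple[SeqRecord, ...]
    universal_window: tuple[int, int]   # ITS3-like window, 0-based half-open
    planted_window: tuple[int, int]     # shifted, host-discriminative window
    variable_region: tuple[int, int]    # host-divergent columns


def make_design_fixture(
    n_targets: int = 10,
    n_hosts: int = 3,
    noise: float = 0.0,
    seed: int = 0,
) -> DesignFixture:
    """Build the planted-discriminator design fixture.

    Targets share a conserved 60-nt region: 18-nt prefix, the universal
    forward window (matched exactly by hosts), a 4-nt extension where hosts
    diverge from targets by 2-4 substitutions (>=1 in its final two
    positions), and an 18-nt suffix.  ``noise`` applies independent random
    substitutions at that per-base rate to every target and host copy.
    """
    rng = np.random.default_rng(seed)
    universal = ITS3.sequence                  # 20 nt, concrete
    ext = "GAAA"                               # target extension columns
    prefix = _random_seq(rng, 18)
    suffix = _random_seq(rng, 18)
    core = prefix + universal + ext + suffix
    u_start = len(prefix)
    u_end = u_start + len(universal)
    ext_start, ext_end = u_end, u_end + len(ext)
    shifted_len = len(ITS3_CORALF)
    planted = (ext_end - shifted_len, ext_end)

    def noisy(seq: str) -> str:
        if noise <= 0:
            return seq
        out = list(seq)
        hits = rng.random(len(seq)) < noise
        for j in np.flatnonzero(hits):
            out[j] = _BASES[int(rng.integers(0, 4))]
        return "".join(out)

    targets = tuple(
        SeqRecord(id=f"dtarget_{i + 1:03d}", sequence=noisy(core),
                  lineage=Lineage((("kingdom", "Fungi"),)), origin="target")
        for i in range(n_targets)
    )
    hosts = []
    for i in range(n_hosts):
        ext_host = list(ext)
        k = int(rng.integers(2, 5))            # 2-4 divergent positions
        final2 = [len(ext) - 2, len(ext) - 1]
        first = final2[int(rng.integers(0, 2))]
        others = [p for p in range(len(ext)) if p != first]
        chosen = [first] + (list(rng.choice(others, size=k - 1, replace=False))
                            if k > 1 else [])
        for p in chosen:
            p = int(p)
            ext_host[p] = [b for b in _BASES if b != ext[p]][int(rng.integers(0, 3))]
        host_core = prefix + universal + "".join(ext_host) + suffix
        hosts.append(
            SeqRecord(id=f"dhost_{i + 1:03d}", sequence=noisy(host_core),
                      lineage=Lineage((("kingdom", "Animalia"),
                                       ("class", "Anthozoa"))),
                      origin="host")
        )
    return DesignFixture(
        targets=targets, hosts=tuple(hosts),
        universal_window=(u_start, u_end),
        planted_window=planted,
        variable_region=(ext_start, ext_end),
    )
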