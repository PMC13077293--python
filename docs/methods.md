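# Methods

## The problem and the model

Universal fungal ITS primers anneal to conserved rRNA genes (18S/5.8S/28S)
that are highly homologous between fungi and their animal hosts. In
host-rich samples — coral tissue is the motivating case — this leads to
overwhelming co-amplification of host rDNA and the loss of nearly all
sequencing reads to the host. One remedy is a *clade-selective* forward
primer: shift a universal primer's binding window a few bases 3′-ward so
that its 3′ terminus comes to rest on positions where host and target
sequences differ. Because 3′-terminal primer-template mismatches
disproportionately block polymerase extension, two or more of them — with
at least one under the final two bases — can abolish host amplification
while target coverage is largely retained.

`cladeprimer` models this with a deliberately simple, fully deterministic
in-silico PCR predicate. For a primer *p* (length *k*, 5′→3′) and a
template placement window *w*:

* positions are compared set-wise over IUPAC codes. In the default
  *intersection* mode, position *i* matches iff
  base_set(p\[i\]) ∩ base_set(w\[i\]) ≠ ∅; *strict* mode additionally
  requires the template base to be concrete. Intersection mode mimics the
  permissiveness of real annealing (a primer R pairs with a template N);
  strict mode gives conservative coverage estimates.
* the final `anchor_len` primer positions (default 2) form a hard 3′
  anchor: any mismatch there disqualifies the placement outright,
  regardless of budget. This encodes "mismatches excluded from tolerance"
  as *must match exactly*; the alternative reading (anchor mismatches are
  free) would make terminal mismatches meaningless and could not produce
  complete host exclusion.
* outside the anchor, up to `mismatch_budget` mismatches (0–2 in the
  standard evaluation) are tolerated. Matching is ungapped: the rule is
  stated purely in substitutions, which is standard in-silico PCR
  practice.

A template *amplifies* under a policy iff some placement has an intact
anchor and a non-anchor mismatch count within budget. `scan_template`
evaluates every placement (vectorized via a 4-bit base encoding; codes
are compatible iff their bit patterns intersect) and returns the
fewest-mismatch qualifying site, leftmost on ties; if none qualifies it
returns the overall minimal-mismatch placement flagged non-qualifying, so
reports can show near-misses. Forward primers scan the deposited sense
strand only by default — curated ITS references are consistently oriented
— with a `both` option for unoriented inputs. Reverse primers scan their
reverse-complement footprint, the anchor applied to the primer's own 3′
end (which faces the insert). Pair mode requires a qualifying forward
site, then the nearest qualifying reverse site downstream within
`max_amplicon_len` (default 2000 nt), yielding the shortest amplicon.

Coordinates are 0-based half-open internally and 1-based inclusive in all
user-facing reports.

## Coverage

`coverage_table` applies the single-primer call to every record and
reports percent amplified per (primer, budget). One scan per record
serves all budgets: amplification at budget *b* is equivalent to the
minimal anchor-intact mismatch count being ≤ *b*, which also makes budget
monotonicity structural. Records shorter than the primer stay in the
denominator as non-amplified — the denominator is the reference-set size.
Stratification partitions records by one taxonomic rank; records missing
the rank are reported under an explicit "unidentified" bucket so
per-taxon totals always reconcile. Percentages print to 2 decimals,
half-even; reports are byte-stable for identical inputs and carry a
policy snapshot plus an order-insensitive content hash of the input set.

## Primer design

The designer generalizes the shift procedure. Inputs are an aligned
target set and a host set (unaligned is fine — host sites are located by
best-total-mismatch placement, not by alignment column).

1. **Consensus.** Each alignment column collapses to the majority base if
   its frequency ≥ `consensus_threshold` (default 0.9), else to the
   minimal IUPAC code covering bases at frequency ≥ `minor_freq` (default
   0.05). Ambiguous template codes count fractionally. Gap-majority
   columns are dropped, with a map back to alignment columns.
2. **Enumeration.** Every window of length 17–22 (configurable within the
   primer bounds 10–40) and degeneracy ≤ `max_degeneracy` (default 4) is
   a candidate.
3. **Scoring.** Target coverage at budgets 0/1/2 via the coverage module
   (the stored values are definitionally consistent with
   `coverage_table`); per host, the best-mismatch site's mismatches
   within the candidate's final `terminal_window` positions (default 4 —
   the span a four-base 3′ shift brings over host-variable positions) and
   within the final 2. A candidate qualifies iff every host shows ≥
   `min_terminal_mismatches` (default 2) in the terminal window, ≥ 1 of
   them in the final two when `require_final2` (default on), and QC
   passes: GC 30–70%, Tm 50–65 °C, homopolymer run ≤ 4, degeneracy ≤ cap.
4. **Ranking** is lexicographic, not a weighted sum, so the order is
   reproducible and explainable: min-over-hosts final-2 mismatches ↓,
   min-over-hosts terminal-window mismatches ↓, coverage at budget 0 ↓,
   degeneracy ↑, leftmost window. Unqualified candidates are listed after,
   flagged with their failure reasons, never silently dropped — the QC
   bounds are advisory.

Tm defaults to a nearest-neighbor thermodynamic estimate at standard salt
(Biopython's implementation), averaged over concrete expansions for
degenerate candidates; the simple 2+4-degree rule is available
(`tm_method="wallace"`) and is used automatically above 64 expansions.
GC counts degenerate codes fractionally by set composition.

## Synthetic fixtures

All generators are pure functions of a spec and a seed (numpy
`default_rng`; no global state) and therefore byte-reproducible.

* **Targets** are flank + forward site + insert (150–450 nt, ITS2-like) +
  reverse-complement reverse site + flank. The forward site is mutated
  per a spectrum — by default 7 exact, 2 with one non-anchor mismatch, 1
  with a 3′-anchor mismatch out of 10 — giving known coverage of
  70/90/90 % at budgets 0/1/2. Flanks and inserts are rejection-sampled
  to contain no accidental qualifying site, and every record's realized
  profile is verified post hoc with the matching engine; the planted
  truth ships as a manifest.
* **Hosts** carry the coral-like pattern at the designed primer's locus:
  2–4 substitutions inside the primer's final four positions, at least
  one under the final two — sites that can never amplify under the anchor
  rule. They also carry an intact universal-primer site, so universal
  forward primers amplify 100 % of the same hosts the designed primer
  excludes, reproducing the qualitative structure of a host-exclusion
  evaluation. With `host_require_final2` off, the substitutions are kept
  outside the final two when possible, producing "leaky" hosts that
  amplify once the budget reaches the mismatch load.
* **Mock community** records (default 10 species) contain exact sites for
  the designed and the universal primers — a positive control that any
  evaluated primer must call fully amplified.
* The **design fixture** plants a 60-nt conserved region holding a
  universal-style window that hosts match exactly and, four positions
  3′-ward of its terminus, a shifted window whose final bases overlie the
  host-divergent columns. Optional per-base substitution noise (2 % in
  the robustness checks) perturbs each copy.
* `simulate_library` draws reads multinomially over pool templates whose
  pair-call succeeds, weighted by copy number. It is an all-or-nothing
  idealization — no partial priming efficiency, no chimeras, no length or
  quality effects — and is a qualitative tool only.

What the fixtures do *not* emulate: real 5.8S/ITS2 sequence composition
and secondary structure, rDNA copy-number variation, divergent
pseudogenes with reduced mismatch load, polymerase-specific extension of
mismatched 3′ ends, and PCR stochasticity. Passing tests therefore
demonstrate that the *rules* are implemented exactly as stated, not that
the rules predict wet-lab outcomes for any particular taxon.

## Numerical and procedural choices

* Half-even rounding to 2 decimals for printed percentages; raw ratios
  are used in all comparisons.
* Tie-breaks are deterministic everywhere: leftmost site at equal
  mismatch count; primary orientation preferred in both-strand scans;
  stable lexicographic candidate order.
* Degenerate positionwise matching makes a degenerate primer's mismatch
  count equal the minimum over its concrete expansions (positions are
  independent); this is asserted by test, not assumed.
* Degenerate inputs: a primer longer than its template yields "no site,
  not amplified"; an empty record set is rejected rather than reported as
  0/0; zero-length inserts (adjacent footprints) are legal.
* Problem sizes in the verification script: 1000 random primer/template
  pairs for engine-vs-enumeration agreement, 500 degenerate-expansion
  cases, 30 hosts, 20 noiseless and 100 noisy design replicates, one
  50,000-read simulation — sizes chosen so the whole run completes in
  under a minute on one core while keeping binomial noise on the reported
  rates below a percentage point.

## Known limitations

* No thermodynamic annealing model (ΔG, dimers, hairpins) and no
  amplification-efficiency model: the call is binary by design, and a
  "excluded" verdict means the placement rules fail, not a measured
  efficiency of zero.
* Ungapped matching ignores primer-template bulges.
* The designer searches single forward primers against a fixed reverse
  primer; no pair co-design, multiplexing, or probe design.
* The ranking is one defensible order among several; it is not claimed to
  reproduce how any published primer was originally found.
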