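# Methods

This note records the modeling choices behind `alzmood`: what is assumed,
which parameters matter, what the synthetic generator does and does not
emulate, and where the design was genuinely open.

## Ontology model

The ontology is a set of named classes under a single synthetic top
concept (`Thing`, mirroring `owl:Thing`), an acyclic set of (child,
parent) subclass edges, object properties, per-class text annotations, and
typed individuals. Acyclicity is re-checked on every edge insertion and
again on load, so a cyclic subclass declaration can never enter a model.

Two fixtures ship because the source material describes the hierarchy in
two non-identical ways: a full observational taxonomy (7 classes, 36
subclasses) used for the structural counts, and a leaner operational
schema (`Patient`, `Scene`, `Pattern`, `State`; 4 classes, 24 subclasses)
used for instance attachment and reasoning. We deliberately ship both
rather than merge them: the subclass spellings differ (e.g. *Boring* vs
*Bored*, *Wander* vs *Wandered*) and collapsing them would invent a
reconciliation the domain model does not define.

Class labels may contain spaces and "/" characters; IRIs are minted by a
deterministic label→fragment map (non-alphanumeric runs become a single
underscore) and the original label is preserved as `rdfs:label`, so
round-tripping through RDF/XML or Turtle reproduces the logical content
exactly. The "at-least-one" link from each `State` subclass to its
evidencing `Pattern` subclasses is encoded as an `owl:Restriction` with
`owl:minQualifiedCardinality 1` on a shared `hasPattern` property, one
restriction per (state, pattern) pair.

The reasoner is intentionally minimal: reflexive-transitive subsumption by
graph reachability, instance checking as subsumption of the asserted
type, transitive-closure hierarchy export, and validity audits. No
tableau-based DL reasoning is attempted; the OWL export exists precisely
so an external DL reasoner can be used for cross-checking.

## Pair-code classification and edit distance

The nine-entry pair table is the semantic core: every ordered pair of
pose letters maps to exactly one mood, so sliding-pair classification of
a clean stream is total and deterministic. Windows are classified by
nearest canonical template under the restricted (optimal-string-alignment)
Damerau–Levenshtein distance: unit-cost insertions, deletions,
substitutions and adjacent transpositions, each substring participating
in at most one transposition. The implementation is the standard
three-row dynamic program; the test suite checks it against an
independently written memoized recursive enumerator on every string pair
up to length 5 over {C, S, P}, plus symmetry, identity-of-indiscernibles
and triangle-inequality properties on randomized inputs.

Canonical templates are each mood's pair code repeated to length 4
(`CCCC`, `CSCS`, `SSSS`, `CPCP`, `SPSP`, `PPPP`). Length 4 aligns the
wandering template with the rule engine's ≥4-run threshold; templates are
tiled or truncated to the window length before comparison, so windows of
any length ≥1 are classifiable. Ties are broken by a fixed, documented
priority (wandering > nervous > depressed > disoriented > bored > none);
`classify_window(..., return_all=True)` exposes the full distance map so
ties remain visible. Overlapping pairs (step 1) are the default reading
of the sliding classifier; disjoint pairing is available as a flag since
the alternative is defensible.

## State rules

A rule is (mood, allowed patterns, minimum repetitions). A rule fires
iff some maximal run of consecutive events, all of whose patterns lie in
the allowed set, reaches the threshold. "Repeated at least 4 times" for
wandering is read as four *consecutive* walking observations — a sustained
directionless walk, consistent with the clinical conceptualization of
wandering; a non-consecutive (total-count) interpretation is available
behind `consecutive=False`. Firings are monotone in the data: appending
events can only add asserted states.

Moods are not mutually exclusive at patient level. The domain model
suggests a single state per patient but gives no arbitration, so the
engine preserves all firings and reports the highest-priority one as
`primary_state`.

The pair table and the rule set disagree on which patterns evidence
nervous (pair codes involve walking+sitting, rules say sitting+standing)
and disoriented (walking+standing vs sitting+standing), and "none" exists
only in the pair table. `audit_rule_consistency` computes and reports
these per-mood discrepancies rather than resolving them; the `audit` CLI
command exits nonzero when any disagreement exists.

`min_trigger_run` is measured empirically — it probes the engine with
runs of k = 1, 2, 3, … qualifying events until the mood asserts — so it
tests the engine's behaviour rather than echoing the rule's field.

## Ingestion

Observation sheets arrive as CSV or XLSX with columns time, pose, status,
and optionally scene and patient (names case-insensitive, remappable via
JSON config). Times are `H:MM:SS` strings or bare integer seconds; pose
is a numeric code decoded through an injective code map defaulting to
1→C (walking), 2→S (sitting), 3→P (standing) — the patterns' canonical
listing order, since no explicit numeric assignment is defined — with
pose letters also accepted directly. Duplicate timestamps within a
patient are an error, never a silent merge; recorded status strings are
preserved verbatim (with a warning for unrecognized spellings) and treated
as ground-truth evaluation labels, not as something the classifier must
reproduce row-by-row — the recorded labels in the source material are not
consistent with any single pair-reading of the pose column.

## Synthetic data

The generator emulates the study conditions: 147 patients of both sexes
(a 45-patient preset mirrors the recorded subset), men aged 75–86 and
women 75–89 (uniform integers within the inclusive ranges), one pose per
second for 60 seconds per stream. The sex ratio defaults to 0.5, a
choice made once in the absence of a stated ratio. Each stream is its
true mood's template tiled to length, then corrupted by i.i.d.
substitution noise (probability `noise_rate` per event of drawing a
uniformly random *other* letter); insertions and deletions are excluded
because the observation grid is fixed-rate. Mood→template assignments
follow the pair-code table (not the state rules) so classifier recovery
is well-defined; datasets assign moods multinomially from configurable
mixing proportions, defaulting to uniform. All generation flows from
`numpy.random.default_rng` seeds; per-stream seeds are derived from the
dataset seed, so identical configs give byte-identical output.

What the generator does **not** emulate: real pose-estimation error
structure (bursty, scene-dependent), within-stream mood transitions,
class imbalance of real cohorts, and any correlation between demographics
and mood. Passing recovery tests therefore demonstrates internal
consistency of classifier and generator under the stated noise model, not
field accuracy on real video-derived data.

## Analytics

Per-patient mood-frequency matrices hold each patient's fraction of
classified pairs per mood (rows sum to 1). PCA is centered (scikit-learn,
full SVD) on these per-patient frequencies — the per-event-indicator
alternative can be had by building the matrix from single-pair streams.
Explained-variance sums are reported for component pairs (1,2), (2,3),
(1,3), the projections a biplot would display; the numeric tables, not
rendered plots, are the tested surface. "No observation" is identified
with the PP/"nothing" category throughout. Degenerate inputs (fewer than
2 patients, zero variance, more components than dimensions) raise rather
than returning NaNs.

## Problem sizes and numerical choices

The test suite and the acceptance script use: all string pairs up to
length 5 for the edit-distance oracle; the full 6-mood × lengths-4..60
grid for noise-free recovery; 600 streams at 10% noise for the noisy
recovery bound (accuracy > 0.9, a regression bound on the generator's
conditions, not an external claim); 147-patient cohorts for the
end-to-end pipeline. Percentage sums are checked to 1e-6, PCA against the
eigendecomposition oracle to 1e-8, loadings compared up to sign (the
usual eigenvector ambiguity). Seeds are fixed in tests; the acceptance
script takes its seed on the command line and derives all randomness from
it.

## Known limitations

- The mini-reasoner covers only the services used here; arbitrary OWL
  constructs in external documents are ignored on parse rather than
  interpreted.
- The pair-table/rule-set disagreement is surfaced, not resolved; users
  choosing one source over the other must say so in config.
- Canonical templates assume stationary, single-mood windows; streams
  mixing moods are classified to the nearest single template.
- Recorded status labels are evaluation data only; no learning from them
  is implemented.
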