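# Methods

This note documents the models, conventions and numerical choices behind
`procoding`, in the order the pipeline uses them: the item-code grammar, the
performance indicators, the reliability estimator, and the synthetic-data
generator with its analytic oracles.

## Item-code grammar and canonicalization

An IPC item code is `appraisal "_" concept (relation concept)*` with
appraisal ∈ {R, E}, concept domains ∈ {I, B, S, P, X} and relations
∈ {`*` directed interaction, `/` forced choice, `,` conjunction}; the
string `nc` is the sentinel for an item whose content cannot be classified
at all. Composite codes attach an ICF category code or an `nd-` placeholder
to concept slots. The canonical serialization wraps specifications in
square brackets (`R_B[b28013]*S[d760]`); a bare concatenated dialect
(`R_Bb28013*Sd760`) is accepted on input because domain letters are
upper-case and ICF components lower-case, which keeps the grammar
unambiguous. Codes are case-sensitive throughout. ICF qualifier suffixes
(severity ratings such as `.2`) are rejected: they play no role in content
linking. Open-ended (X) concepts may carry `nd-` specifications but never a
concrete ICF code — a concept that genuinely spans several domains is by
definition not singly linkable.

**Directionality.** `*` is ordered: `R_B*S` (a biological concept impacting
a social one) differs from `R_S*B`. `/` and `,` are treated as
order-insensitive, so that overlap detection does not split semantically
identical codes such as `R_B,S` and `R_S,B`; the coding rules themselves do
not legislate this, so it is a package-level convention.

**Canonical form.** Relations chain left-to-right with no precedence, so
`A,B*C` reads `(A,B)*C`: only the *leading* maximal run of one repeated
order-insensitive operator is a genuinely unordered set. Canonicalization
sorts exactly that run by (domain letter, spec string) and leaves every
later concept bound to its position. Sorting overlapping operator runs is
not idempotent (consider `R_I/I,B`), and sorting past an operator change
silently rewires which concept the following operator applies to, so the
leading-run rule is the largest sound normalization. Every homogeneous code
— including all forms the coding rules illustrate — is fully sorted by it.
ICF code lists are canonicalized by plain alphanumeric sort. Canonical
forms are compared as strings everywhere downstream.

A code is *fully classified* iff it is not `nc` and carries no `nd-`
specification. A pure IPC code without specifications is fully classified:
the IPC framework classifies open-ended content as X rather than leaving it
uncodable.

## Performance indicators

All indicators operate on a two-rater dataset (the supported design) after
canonicalization.

* **Percent agreement**: share of items with identical canonical codes.
* **Classification capacity**: share of items that agree *and* are fully
  classified. By construction capacity ≤ agreement, with equality exactly
  when every item is fully classified.
* **Coding efficiency**: unique canonical codes across the final per-item
  codings — whole item codes for IPC/composite, individual ICF/`nd-` codes
  for the ICF framework — split into valid and rater-generated
  (`nc`, containing `nd-`) codes.
* **Content overlap**: share of items whose match key (whole code, or any
  single ICF code in the list) also occurs in another item. The top-k
  variant admits only the k most frequent codes as match keys and still
  requires ≥ 2 carrying items; ties at rank k break alphanumerically. The
  two natural readings of "overlap detected by the top-k codes" coincide
  whenever every top-k code occurs at least twice, which is the typical
  regime; the implemented reading (a top-k code must still be shared)
  is the conservative one.

**Final codings.** Efficiency and overlap need one code per item. When the
table carries a `consensus` pseudo-rater, that column is used; otherwise
the item's code is the agreed canonical code, and disagreeing items are
excluded from the counts and listed in the report (`unresolved_items`).
Capacity and agreement are always computed from the independent rater
columns. Percentages are carried at full precision and rounded to one
decimal only for display.

## Krippendorff's α

Reliability is estimated per framework on nominal labels = canonical *full*
item codes (the whole composite code, or the sorted ICF code list),
rater-generated codes included as ordinary labels — disagreeing values are
kept as distinct labels, since that is what they are. For each unit with
m ≥ 2 pairable values, every ordered pair of values from distinct coders
adds 1/(m−1) to the coincidence matrix; with margins n_j and total n,

    D_o = Σ_{j≠k} o_jk / n,   D_e = Σ_{j≠k} n_j n_k / (n (n−1)),
    α = 1 − D_o / D_e.

α = 1 iff observed disagreement is zero; when every value in the data is
one single label, D_e = 0 and α is undefined, which the package signals
with a dedicated exception rather than a sentinel value.

**Bootstrap.** Confidence intervals resample *units* (items) with
replacement, recompute α per replicate, and take the percentile interval
(95%, 1000 replicates by default; `confidence=0` degenerates to the median
replicate). Unit-level resampling is simpler and statistically defensible
compared to resampling coincidence pairs, and is fully determined by the
seed recorded in the result. Replicates with undefined α are redrawn within
a 10× draw budget; if more than half of all draws are degenerate the
interval is flagged `unstable`. Percentile intervals (not BCa) match the
plain "95% CI" contract.

## Synthetic data generator

The generator emulates a pooled HRQoL item sample with known truth:

* **Concept count** per item: truncated geometric on {1..max_concepts}
  (weights q^(k−1)), with q solved numerically (Brent's method) so the
  truncated mean equals `mean_concepts`. Defaults: mean 1.7, max 3. Only a
  mean is a defensible target here; the law is the simplest monotone family
  on a bounded support.
* **Domains** are drawn from `domain_probs` (defaults I 0.06, B 0.37,
  S 0.22, P 0.35 — HRQoL content leans biological/psychological), with zero
  base mass on X: open-endedness arises through the unclassifiability
  mechanism below, which keeps the unclassifiable item fraction exactly at
  its parameter. Appraisals are rational with probability 0.8; relations
  draw from {`*` 0.5, `/` 0.2, `,` 0.3}.
* **Unclassifiable content**: with probability `p_icf_unclassifiable`
  (default 0.31) an item has one uniformly chosen concept replaced by an
  `nd-` placeholder; half of those become open-ended X, half stay in their
  domain (a vague within-domain concept). All other concepts draw ICF
  specifications uniformly from the code pool.
* **Code pool**: 60 bundled synthetic, structurally valid ICF-style codes
  spanning the b/s/d/e components with sibling groups (no category text is
  redistributed). A user pool can be substituted.
* **Rater error model** (independent per rater and element): appraisal flip
  (`e_appraisal`), relation resample from the relation distribution
  (`e_relation`), domain resample among the four concrete domains
  (`e_domain` — open-endedness is a classifiability judgment, not a domain
  confusion), ICF specification replaced by a uniformly chosen sibling —
  same parent, falling back to same chapter (`e_icf_substitute`) — and a
  whole-item `nc` lapse (`e_nc`). A rater who codes an item `nc` emits the
  single placeholder `nd-nc` as their ICF row, since ICF codings must be
  non-empty. Default rates are 0.005 each, which places simulated percent
  agreement in the high-90s regime typical of trained rater pairs working
  from discussed classification rules.

Each rater's IPC, ICF and composite rows derive from one perturbed
composite code, so the three frameworks stay mutually consistent. All draws
flow from one seed via separate child streams for the bank and the raters;
identical seeds give byte-identical output tables.

**Closed-form oracle.** Under this model the probability that both raters
produce identical, fully classified codes factorizes over elements. With
per-element agreement terms

    A_app = (1−e)² + e²,
    A_cat(p, e) = Σ_t p_t [((1−e) + e p_t)² + Σ_{v≠t} (e p_v)²]
                  (relation and domain resampling),
    A_spec = mean over the pool of (1−s)² + s²/k  (k = sibling count),

expected composite capacity is
`100 (1−p_uncl)(1−e_nc)² Σ_c P(c) A_app A_rel^{c−1} (A_dom A_spec)^c`, and
analogous products hold for IPC (specs stripped; an X-domain truth concept
agrees with probability (1−e)² + e² Σ p'²) and for the ICF code list
(domains irrelevant). `expected_capacity` implements these and the test
suite holds simulations at n = 2000 to within Monte-Carlo tolerance
(±3 points) of them.

**What the generator does not emulate** — and therefore what passing tests
do and do not show: real item semantics and the linguistic ambiguity that
drives actual rater disagreement; correlated (systematic) rater errors —
the model's errors are independent, so chance-corrected agreement is, if
anything, optimistic; consensus-building dynamics after independent coding;
instrument-level clustering of content (items are exchangeable here, so
whole-code overlap rates run lower than in real questionnaires, which reuse
stems and response structures heavily); and the 2019 revision of the ICF
linking rules, which is out of scope throughout the package.

## Numerical and interface choices

* Ties in top-k code ranking break by alphanumeric code order.
* Metrics are invariant to item order and rater labels; datasets validate
  that each (item, rater, framework) triple is unique and that raters cover
  equal item sets per framework.
* Degenerate inputs fail loudly: empty tables, >2 raters for the two-rater
  indicators, `top_k ≤ 0`, undefined α.
* Parse errors always name the offending token and character position.
* Problem sizes in the test suite were chosen to make sampling error small
  relative to the asserted tolerances while keeping the suite fast:
  exhaustive oracle comparison over all 4096 three-item two-rater datasets
  per framework variant plus 1000 sampled larger ones; simulation checks at
  n = 2000 items; reliability dual-route checks on 120+ random tables at
  1e-10; a 10⁴-string fuzz corpus for the grammar.
* The command-line interface is a thin layer over the library; everything
  it prints comes from `MetricsReport`/`AlphaResult` objects that are also
  available programmatically, and JSON reports carry full precision plus a
  provenance block (seed, config digest, version).
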