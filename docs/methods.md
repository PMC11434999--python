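# Methods

## Data model

A FAERS-style quarterly extract is three dollar-delimited tables keyed
by a report identifier (`primaryid`): DEMO (one row per case version,
with age value, age-unit code, and gender), DRUG (one row per drug
mention), and REAC (one row per MedDRA preferred term, PT). A case may
be resubmitted; versions share a `caseid`.

Deduplication keeps, per case, the row with the highest `caseversion`
(ties broken by the lexicographically highest `primaryid`) — the FAERS
convention that later submissions supersede earlier ones — and collapses
exact-duplicate DRUG/REAC rows. The analysis table ("Table A") is the
inner join of the three deduplicated tables on the report id: a report
missing from any table is excluded. Drug and PT names are matched after
normalization (case-fold, trim, collapse whitespace); there is no fuzzy
matching or spelling correction, on the assumption that generic names
were curated upstream.

The event vocabulary is the "taste and smell disorders" SMQ (20000046,
MedDRA v25.0) minus congenital anosmia: seven taste PTs and seven smell
PTs. A report is a case if it carries at least one such PT; taste-only /
smell-only / both partitions are over distinct reports.

The demographic table ("Table B") restricts to reports mentioning at
least one ATC L01 (antineoplastic) drug and applies the cleaning rules:
ages recorded in years are kept as-is and decade codes are multiplied by
10, while month/week/day/hour codes are **dropped, not converted** (the
record is treated as "age not given in years"); ages outside [0, 120]
and unknown genders are removed.

## Disproportionality

Exposure × event cross-classification of all Table A reports gives the
2×2 table (a, b, c, d); the background "all other reports" is the whole
database, including reports of unrelated drugs. Conventions, chosen to
keep a single tested code path for drugs, classes, and strata:

- **ROR and CI** are computed on the Haldane-corrected table (+0.5 per
  cell) for per-drug and per-class screening, where zero cells are
  common; for demographic strata, whose cells are large and zero-free,
  the uncorrected counts are used (both agree to three decimals on such
  tables).
- **Fisher's exact p** is always computed on the raw integer counts
  (the exact test is defined on integers; the correction exists to make
  the odds ratio computable). Two-sided p is the sum of hypergeometric
  probabilities of tables no more probable than the observed one
  (scipy's convention, matching R's `fisher.test`).
- **Wald 95% CI**: exp(lnROR ± z·√(1/a+1/b+1/c+1/d)), z = 1.959964.
  This reproduces published demographic intervals from their printed
  cells to ±0.001.
- **−log10 p is capped at 308** (double-precision underflow); p = 0
  maps to the cap.
- **Signal criteria**: p < 0.05 ∧ ROR > 1 ∧ a ≥ 100, all configurable
  (`SignalCriteria`). The count threshold is inclusive (≥ 100).
- No multiplicity adjustment is applied across drugs, reproducing
  standard practice in descriptive disproportionality screens; with
  hundreds of drugs, individual signals must be read as hypothesis-
  generating. The null-calibration experiment (below) quantifies the
  resulting false-signal rate under the bundled conditions (~2.5%,
  because the ROR > 1 criterion halves the two-sided 5%).

A note on the Haldane correction's direction: the correction does *not*
universally shrink the ROR toward 1. It does whenever the diagonal sum
does not exceed the off-diagonal sum (a + d ≤ b + c), and in the
pharmacovigilance regime — d (background non-events) vastly larger than
every other cell with small a — the practical effect is shrinkage;
but tiny near-degenerate tables such as (200, 1, 199, 1) move slightly
away from 1. The property test asserts the condition-qualified
statement.

## Demographics and class analysis

Age is dichotomized at 70 years (≥ 70 is "elderly"; the cutoff is a
parameter), gender as male vs female; each split is analyzed with the
same ROR/Fisher/Wald machinery, group 1 playing the exposure row.
Class-level analysis treats "exposed" as "mentions ≥ 1 drug of the
class"; a report exposed to several classes counts in each class's
table, which are computed independently. The per-class signal fraction
is 100·(signal drugs in class)/(mapped drugs in class), reported to two
decimals. The bundled drug → ATC map is illustrative; real runs supply
a complete curated map.

## Profile clustering and PCA

Signal drugs are profiled by the Haldane-corrected lnROR against each
retained PT. PT columns are retained when their database-wide
(all-drugs) report count reaches a floor: 3000 at full-FAERS scale
(≈12.3M joined reports), which keeps the seven frequent chemosensory
terms; for synthetic databases the floor is rescaled by database size
(same per-report prevalence cut, e.g. 49 at 200,000 reports). Cells are
finite by construction. Rows are *not* standardized before clustering —
cells already share the lnROR scale — though the matrix is a plain
DataFrame and callers can standardize if desired.

Ward clustering uses scipy's minimum-variance agglomeration on
Euclidean distances; at each step the merge minimizing the increase in
within-cluster sum of squares, |A||B|/(|A|+|B|)·‖c_A − c_B‖², is taken.
scipy's nearest-neighbor-chain algorithm is deterministic; on continuous
data ties have probability zero, and the merge sequence provably equals
exhaustive search (verified against a brute-force agglomerator on
hundreds of random matrices). The flat assignment cuts the dendrogram
at k clusters (default 3).

PCA is an eigendecomposition of the column correlation matrix
(columns standardized with the sample sd). Components are ordered by
decreasing eigenvalue; explained fractions are eigenvalues over their
sum (= number of PTs) and sum to 1. Because eigenvector signs are
arbitrary, each component is oriented so its largest-magnitude loading
is positive; interpretation is by the Pearson correlation (with
two-sided p) of component scores against each PT's lnROR column, and
the first component is validated by an OLS regression of its scores on
the per-drug lnROR of the combined 14-PT event.

## Synthetic data generator

The generator emulates the statistical structure of a FAERS extract,
not its content: per report it draws age from a three-component normal
mixture (weights 0.25/0.55/0.20, means 40/62/76, sd 12/10/7 years,
clipped to [0, 100]; ≈28% aged ≥ 70), gender (55% female), an
independent Bernoulli drug set, and an independent Bernoulli PT set.
Associations are injected on the **odds scale**: a report exposed to a
drug with target ROR r on a PT has that PT's odds multiplied by r. This
makes the population ROR of the (drug, PT) pair equal r exactly —
p₁/(1−p₁) = r·p₀/(1−p₀) regardless of the mixing of other covariates —
which is what makes parameter-recovery experiments well defined. A
configured age effect multiplies the odds of every SMQ PT for patients
aged ≥ 70; the per-PT age odds ratio is then exactly the target, while
the *combined* (any-SMQ-PT) odds ratio aggregates a few percent above
it, because a union of independently tilted rare events is slightly
super-multiplicative. Tests therefore check the per-PT ratio exactly
and the combined ratio with a wider band.

Dirty data mirror the cleaning rules: 5% of cases are re-emitted as a
superseded earlier case version (removed again by deduplication), 6% of
DEMO rows get an unusable age (month-coded, out-of-range, or missing),
2% are decade-coded (valid after ×10), and 2% have unknown gender.
Every report gets at least one drug mention and one reaction (fallback
filler entries), as in real FAERS. Ten non-SMQ filler PTs and five
background co-medications keep the "all other reports" background
non-degenerate. A `GroundTruthLedger` retains the realized indicator
matrices, so any downstream 2×2, report count, or Table B row set can
be compared with the file pipeline **exactly** — the round-trip
equality is asserted in tests.

Default conditions (chosen once as a realistic desk-scale emulation):
200,000 reports; 21 antineoplastic drugs, three per L01 subclass at
exposure 1/2/3%; SMQ PT baselines mirroring the relative frequencies of
a real snapshot (dysgeusia 1.5% down to hyposmia 0.04%, instrumental
and hallucination terms ≤ 0.01%), so the report-count floor retains
exactly the seven frequent PTs. What the generator does **not**
emulate: reporting-bias dynamics (notoriety/Weber effects), co-
medication confounding (exposures are independent), MedDRA term
hierarchies, and real marginal drug frequencies — so passing tests
validate the *machinery* (counting, correction, testing, clustering,
recovery of known effects), not robustness to those real-data
phenomena.

## Calibration experiments (problem sizes)

- CI coverage: a planted drug–event ROR of 4.0 (drug exposure 2%,
  dysgeusia) at n = 200,000; the Wald 95% CI covers 4.0 in ≥ 93 of 100
  seeded replicates (observed 95/100).
- Null calibration: with all RORs = 1, the signal criteria flag ≤ 10%
  of drugs reaching the report-count floor over 50 replicates
  (observed ≈ 2.4%).
- Profile recovery: three archetypes (uniform +2 lnROR on seven PTs,
  taste-only +2, baseline) at n = 200,000, exposure 3%, six drugs each;
  Ward at k = 3 recovers the partition with Rand index ≥ 0.9 (observed
  1.0) and the second component carries the taste-versus-smell contrast
  with the planted signs on all seven PTs.
- Oracle scans: exact-test agreement with integer hypergeometric
  enumeration on every 2×2 table with total ≤ 60 (max |Δ| ≈ 4e-16);
  Ward merge sequences vs exhaustive search on 200 random ≤ 7-row
  matrices; PCA vs direct eigendecomposition on random 20×7 matrices.

## Numerical and degenerate-input choices

- Unparseable numeric fields become missing, never errors; missing
  required columns raise a schema error naming the column.
- An all-zero uncorrected 2×2 (drug or event absent) is representable;
  the ROR and Wald CI on it instruct applying the Haldane correction
  first, and the corrected all-zero table has ROR 1.
- Double Haldane correction, Fisher on corrected (non-integer) counts,
  PCA on a constant column, clustering with k outside [1, rows], and
  regression with fewer than three drugs are contract violations with
  named errors.
- Fixed seeds make generated files byte-identical and the whole
  pipeline rerun-stable; the run manifest (config echo, stage row
  counts, version, seed) suffices to reproduce any output.

## Known limitations

ROR is a relative reporting signal, not a risk estimate: no denominator
of drug users exists in spontaneous data. The package reproduces the
descriptive screening methodology faithfully — including its lack of
multiplicity and confounding adjustment — and the synthetic validation
shows correctness of the computation, not of causal interpretation on
real FAERS data. Full-database quantities (overall report counts, class
RORs, the published drug clusters) depend on the actual FAERS snapshot
and curation and are out of scope at desk scale.
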