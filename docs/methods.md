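# Methods

## Protocol model

The package is built around a single explicit model of the BrAPI v1 wire
contract, shared by server, client and validator.

**Envelope.** Every response is a JSON object with exactly two top-level
keys, `metadata` and `result`. `metadata` always carries three members:
`pagination` (the four integers `pageSize`, `currentPage`, `totalCount`,
`totalPages`), `status` (a possibly empty array of `{code, message}`
entries — empty, never null, on clean success) and `datafiles` (a
possibly empty array of URL strings). `result` follows one of three
patterns: *master* (flat entity fields, no `data` key), *details*
(exactly one `data` array) or *master/details* (parent fields plus
`data`). Classification is total and disjoint: the presence and
exclusivity of the `data` key decides the pattern, and a `data` value
that is not an array is malformed rather than a fourth pattern.

**Pagination.** Pages are zero-indexed. For positive `pageSize`,
`totalPages = ceil(totalCount / pageSize)` and `len(data) <= pageSize`.
Single-entity responses must carry the all-zero block. One deliberate
reading reconciles two requirements that are in tension: a request for a
page at or past the end answers HTTP 200 with an empty `data` array,
truthful totals and an informational status entry (so naive page
iterators terminate instead of erroring), and the envelope checker
therefore flags `currentPage >= totalPages` only when the page claims a
*non-empty* slice — that combination is arithmetically impossible,
whereas the empty out-of-range echo is legitimate server behavior.

**Error responses.** The standard does not define an error body. Errors
here keep the envelope: all-zero pagination, `result: null`, and one
explanatory status entry whose code is the HTTP status. The envelope
checker accepts a null `result` for this reason.

## Entities and schemas

The standard names field groups (MCPD passport data, trait/method/scale,
plot layout) but not exhaustive key lists, so the shipped JSON schema
files under `src/brapiref/schemas/` are the package's single source of
truth for entity shapes. Conventions applied throughout: camelCase keys;
every `…DbId` identifier serialized as text, never a number; optional
fields emitted as `null` rather than omitted, so schemas can require key
presence with `additionalProperties: false`; timestamps in ISO-8601 with
an explicit UTC offset. The schema dialect is a narrow JSON Schema subset
(`type`, `properties`, `required`, `additionalProperties`, `items`,
`enum`, `minimum`) evaluated by `brapiref.schema`, which reports every
violation in document order so reports are deterministic.

## Synthetic fixture dataset

`brapiref.fixtures` fabricates the dataset the reference server serves.
It emulates the *structure* of breeding data — a program → trial → study
hierarchy with locations and seasons; germplasm with passport fields,
pedigree crosses and progeny links; observation variables as
trait/method/scale triples; plot-level observation units with replicate,
block and grid coordinates; numeric observations drawn uniformly from
each scale's valid range; a SNP marker panel with per-germplasm marker
profiles and an allele matrix (per-locus draws: 0.45 homozygous
reference, 0.45 homozygous alternate, 0.05 heterozygous, 0.05 missing
"-"); a three-linkage-group genetic map; samples on 96-well-style plates
and vendor orders.

What it deliberately does **not** emulate: realistic trait distributions,
genotype–phenotype association, linkage disequilibrium, or any biological
signal. Passing tests therefore demonstrate protocol and referential
correctness, not statistical realism; a client that works against these
fixtures has been exercised against the contract, not against field
data.

Defaults (chosen to be legible and sub-second: a couple of records per
branch of the hierarchy, enough germplasm and markers for multi-page
listings): 2 crops, 2 programs × 2 trials × 2 studies, 4 locations,
25 germplasm, 10 variables, 50 markers, 10 marker profiles (⇒ 500 allele
calls), 20 samples, 1 map, 6 observation units per study. All randomness
flows through one `random.Random(seed)`; names come from fixed in-module
word lists, so a configuration fixes the store byte-for-byte across
platforms and processes. Identifiers are small decimal strings per
entity kind, so `germplasm/1` always resolves.

`MarkerProfile.extractDbId` models a reference into an external lab
system; it has no referent in the store and is excluded from the
referential-closure scan. All other `…DbId` fields (including list-valued
ones) must resolve, and the scan walks every record recursively.

## Server

A plain WSGI application; `wsgiref.simple_server` hosts it for the CLI,
and an in-process transport drives it directly in tests. Routing is
literal-segment matching with `{param}` placeholders; literal routes are
registered before placeholder routes that would shadow them. The roster
is 69 calls in the 16 standard categories, with GET and POST on the same
path counted as distinct calls — that is what makes the per-category
descriptor counts served by `/calls` equal the standard's printed
counts. `/calls` emits one descriptor per (path, method) pair, each with
a non-empty versions list (`"1.0"`, `"1.3"`).

Parameter handling: `page`/`pageSize` are accepted in the query string
and, for POST search calls, in the request body; `pageSize < 1`,
`page < 0` or an unknown filter field map to HTTP 400 (the all-zero
pagination block stays reserved for single-entity responses). The default
`pageSize` is 1000; a configurable cap exists but no cap is applied by
default. Filters are exact-match conjunctions, with membership semantics
on list-valued fields.

Large tables (allele-matrix and phenotype exports) move to server-hosted
TSV/CSV files once they exceed a configurable row threshold (default
10 000; the TSV/CSV phenotype calls always export). The files are served
under `/datafiles/` and referenced from `metadata.datafiles`, so these
calls still answer with a normal JSON envelope.

Auth is pass-through only: open mode, or bearer-token mode that checks
`Authorization: Bearer <token>` against an accepted list and answers 401
otherwise. Token issuance and OAuth2 flows are out of scope. TLS is
likewise out of scope (deploy behind a terminating proxy). Write calls
mutate only the in-memory store and are lost on restart.

Fault injection: five named flags each break exactly one contract aspect
(drop `totalPages`; report `totalPages` one too high; mangle the echoed
identifier on detail calls; serve `text/plain`; add a stray sibling key to
details results). They exist to demonstrate validator sensitivity and to
exercise third-party conformance tooling.

## Client

`Connection` normalizes the base URL to everything before `/brapi` and
never exposes the token in `repr`. Envelope validation on receipt is on
by default with an opt-out (`strict=False`) for tolerant interop.
`iterate_all` trusts `totalPages` for its loop bound and stops at
`currentPage == totalPages - 1`; a `totalCount` that drifts between pages
is surfaced in the iterator's `warnings` list rather than raised, since a
live server may legitimately grow mid-walk. There are no automatic
retries — deterministic behavior matters more here than resilience — but
the transport is pluggable, so a retrying transport can be dropped in.

## Validator

The battery only tests what a server advertises: descriptors fetched from
`/calls` gate every case, and an unadvertised call is skipped without ever
being requested. Cases are chained — a search harvests the first
identifier from its response and seeds the matching detail call — and a
missing harvest (failed or skipped source) cascades to *skip*, not
*fail*, so one broken call cannot avalanche the report. The six check
kinds are independent per case: HTTP status, JSON media type, envelope
validity (including pagination arithmetic and expected result pattern),
data types (identifier fields must be text, `data` must be an array),
entity-schema match, and reference match (requested id echoed back,
`currentPage` echoing the requested page, filtered listings containing
only matching records, `germplasm/1` carrying `germplasmDbId` "1").

Results aggregate per REST resource (the call's category); a server is
*compliant* iff zero executed tests fail — all advertised calls count
equally. Reports render as an indented text tree or as loss-less JSON.
Scheduled auditing is a thin CLI loop (`--repeat`/`--interval`) writing
timestamped JSON reports; hosted frontends, stored report history and
e-mail subscriptions are out of scope.

## Numerical and testing choices

Problem sizes are deliberately small: the default fixture makes every
end-to-end test sub-second, the full suite runs in a few seconds, and the
acceptance script in well under a minute. The randomized-closure sweep
uses 20 configurations drawn from a seeded meta-generator; hypothesis
properties run derandomized so failures reproduce. The cross-process
determinism test serializes the store in a second interpreter and
compares byte-for-byte.

## Known limitations

* v1 URL space only; no v2, no JSON-LD contexts, no MIAPPE/MCPD document
  mapping beyond the MCPD-aligned germplasm fields.
* Search calls accept single-valued exact filters (identical sets on GET
  and POST); the multi-valued filter lists some live servers accept are
  not modeled.
* The entity schemas are a faithful minimal core, not the full field
  inventory of any particular production database; validating a
  third-party server checks the keys this package ships schemas for.
* No persistence: the store lives and dies with the process.
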