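# brapiref

A self-contained reference stack for **BrAPI v1**, the community REST
standard for exchanging plant-breeding data (germplasm passports, field
trials, phenotypic observations, genotyping marker data) between breeding
databases and client applications.

Breeding informatics teams implementing or consuming the standard need
three things that are awkward to test in isolation: a known-good server to
develop clients against, a correct paging client to develop servers
against, and an auditor that tells either side exactly where it deviates
from the wire contract. `brapiref` bundles all three around one shared
model of the protocol:

* **reference server** (`brapiref.server`) — a WSGI service exposing the
  complete v1 roster of 69 calls in 16 categories (Calls, Crops,
  Germplasm, Germplasm Attributes, Markers, Marker Profiles, Programs,
  Trials, Studies, Phenotypes, Traits, Observation Variables, Genome
  Maps, Location, Samples, Vendor Samples) under the standard URL grammar
  `http(s)://host[/basePath]/brapi/v1/<call>`, backed by a deterministic
  synthetic breeding dataset;
* **client** (`brapiref.client`) — capability discovery via `/calls`,
  schema-validated page fetches, exhaustive record iteration, bearer-token
  injection;
* **validator** (`brapiref.validator`) — a compliance auditor that
  discovers a server's advertised calls and runs a chained battery of 71
  tests (status code, media type, envelope validity, data types, entity
  schema, request/response reference checks), aggregated per REST
  resource.

## The wire contract

Every call answers with the same JSON envelope:

```json
{
  "metadata": {
    "pagination": {"pageSize": 10, "currentPage": 0, "totalCount": 25, "totalPages": 3},
    "status": [],
    "datafiles": []
  },
  "result": { ... }
}
```

`result` follows one of three patterns — *master* (one entity, no `data`
key), *details* (a single `data` array and nothing else), or
*master/details* (parent fields plus a `data` array of children).
Whenever `data` is present the response is paginated: pages are
zero-indexed, `totalPages = ceil(totalCount / pageSize)`, and the length
of `data` never exceeds `pageSize`. Single-entity responses carry the
all-zero pagination block. Oversized tables move into server-hosted
delimited files referenced from `metadata.datafiles`. Machine-readable
JSON schemas for the envelope and every entity ship in
`src/brapiref/schemas/` and are used by both the server tests and the
validator.

## Worked example

```python
from brapiref import (Connection, ReferenceServer, WSGITransport,
                      fetch_page, run_suite, render_report)

server = ReferenceServer()  # default synthetic fixture, seed 42
conn = Connection("http://demo", transport=WSGITransport(server))

page = fetch_page(conn, "germplasm", page=0, page_size=10)
print(page["metadata"]["pagination"])
first = page["result"]["data"][0]
print(first["germplasmDbId"], first["germplasmName"], first["genus"], first["species"])

detail = fetch_page(conn, "germplasm/1")
print(detail["result"]["germplasmDbId"], detail["metadata"]["pagination"])

report = run_suite(conn)
print(render_report(report).splitlines()[-1].strip())
```

prints

```
{'pageSize': 10, 'currentPage': 0, 'totalCount': 25, 'totalPages': 3}
1 MA001 Zea mays
1 {'pageSize': 0, 'currentPage': 0, 'totalCount': 0, 'totalPages': 0}
overall: COMPLIANT (71 pass, 0 fail, 0 skip)
```

The first line is the pagination block of the opening page of the
germplasm listing (25 fabricated accessions, first page is page zero);
the second is the first maize accession's passport identity; the third
shows that a detail call echoes the requested identifier and carries the
all-zero pagination block; the last line is the validator's verdict on
the bundled server.

The same pieces are available from the shell (`brapiref serve`,
`brapiref get`, `brapiref validate`, `brapiref fixtures generate/check`) —
`brapiref validate <url>` exits 0 for a compliant endpoint, 1 on any
failure, 2 when the endpoint cannot be tested at all. `--fault` flags on
`brapiref serve` start the server with deliberate, named protocol defects
for exercising conformance tooling.

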