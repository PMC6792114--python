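"""Programmatic consumer of any BrAPI v1 endpoint.

A :class:`Connection` pairs a normalized base URL with an optional bearer
token and a transport.  Two transports are provided: a real-HTTP transport
built on :mod:`urllib.request` and an in-process transport that calls a
WSGI application directly (useful for testing clients and servers together
without sockets).  A recording wrapper logs every request it forwards.

Paged retrieval follows the wire contract: pages are zero-indexed, the
``data`` array of each page is bounded by the pagination block, and
iteration stops when ``currentPage`` reaches ``totalPages - 1``.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Any, Iterator, Mapping, Optional, Protocol
from urllib.parse import urlencode, urlsplit

from .core_model import validate_envelope
from .errors import ProtocolError, StatusError, TransportError

__all__ = [
    "Connection",
    "RawResponse",
    "Transport",
    "UrllibTransport",
    "WSGITransport",
    "RecordingTransport",
    "discover",
    "fetch_page",
    "iterate_all",
    "request_raw",
    "PageIterator",
]


@dataclass
class RawResponse:
    status: int
    content_type: str
    body: bytes

    def json(self) -> Any:
        try:
            return json.loads(self.body.decode("utf-8"))
        except (UnicodeDecodeError, json.JSONDecodeError) as exc:
            raise ProtocolError(f"response body is not JSON: {exc}")


class Transport(Protocol):
    def request(
        self, method: str, url: str, headers: Mapping[str, str], body: Optional[bytes], timeout: float
    ) -> RawResponse: ...


class UrllibTransport:
    """Real HTTP transport on the standard library."""

    def request(self, method, url, headers, body, timeout) -> RawResponse:
        import urllib.error
        import urllib.request

        req = urllib.request.Request(url, data=body, method=method)
        for name, value in headers.items():
            req.add_header(name, value)
        try:
            with urllib.request.urlopen(req, timeout=timeout) as resp:
                return RawResponse(resp.status, resp.headers.get("Content-Type", ""), resp.read())
        except urllib.error.HTTPError as exc:
            return RawResponse(exc.code, exc.headers.get("Content-Type", ""), exc.read())
        except urllib.error.URLError as exc:
            raise TransportError(f"request to {url} failed: {exc.reason}")


class WSGITransport:
    """In-process transport that drives a WSGI application directly."""

    def __init__(self, app):
        self.app = app

    def request(self, method, url, headers, body, timeout) -> RawResponse:
        parts = urlsplit(url)
        environ = {
            "REQUEST_METHOD": method,
            "PATH_INFO": parts.path,
            "QUERY_STRING": parts.query,
            "SERVER_NAME": parts.hostname or "testserver",
            "SERVER_PORT": str(parts.port or 80),
            "HTTP_HOST": parts.netloc or "testserver",
            "wsgi.url_scheme": parts.scheme or "http",
            "wsgi.input": io.BytesIO(body or b""),
        }
        if body is not None:
            environ["CONTENT_LENGTH"] = str(len(body))
            environ["CONTENT_TYPE"] = "application/json"
        for name, value in headers.items():
            environ["HTTP_" + name.upper().replace("-", "_")] = value
        captured: dict[str, Any] = {}

        def start_response(status_line, response_headers):
            captured["status"] = int(status_line.split(" ", 1)[0])
            captured["headers"] = dict(response_headers)

        chunks = self.app(environ, start_response)
        payload = b"".join(chunks)
        return RawResponse(
            captured["status"], captured["headers"].get("Content-Type", ""), payload
        )


class RecordingTransport:
    """Wraps another transport and logs every request it forwards."""

    def __init__(self, inner: Transport):
        self.inner = inner
        self.requests: list[dict] = []

    def request(self, method, url, headers, body, timeout) -> RawResponse:
        self.requests.append({"method": method, "url": url, "headers": dict(headers)})
        return self.inner.request(method, url, headers, body, timeout)


@dataclass
class Connection:
    """One BrAPI endpoint: normalized base URL, optional token, transport.

    The base URL is everything before ``/brapi`` (scheme, host and any base
    path).  The token, when set, is attached to every request as an
    ``Authorization: Bearer`` header and is never echoed in ``repr``.
    """

    base_url: str
    token: Optional[str] = None
    timeout: float = 10.0
    page_size: Optional[int] = None
    transport: Transport = field(default_factory=UrllibTransport)
    strict: bool = True

    def __post_init__(self) -> None:
        url = self.base_url.rstrip("/")
        marker = url.find("/brapi")
        if marker != -1:
            url = url[:marker]
        self.base_url = url

    def __repr__(self) -> str:  # token never logged
        return f"Connection(base_url={self.base_url!r}, token={'***' if self.token else None})"

    def url_for(self, call: str, params: Optional[Mapping[str, Any]] = None) -> str:
        url = f"{self.base_url}/brapi/v1/{call.lstrip('/')}"
        if params:
            url += "?" + urlencode(params, doseq=True)
        return url

    def headers(self) -> dict[str, str]:
        out = {"Accept": "application/json"}
        if self.token:
            out["Authorization"] = f"Bearer {self.token}"
        return out


def request_raw(
    connection: Connection,
    call: str,
    params: Optional[Mapping[str, Any]] = None,
    method: str = "GET",
    body: Optional[Mapping[str, Any]] = None,
) -> RawResponse:
    """One HTTP request without validation or error mapping (validator use)."""
    payload = json.dumps(body).encode("utf-8") if body is not None else None
    return connection.transport.request(
        method, connection.url_for(call, params), connection.headers(), payload, connection.timeout
    )


def fetch_page(
    connection: Connection,
    call: str,
    params: Optional[Mapping[str, Any]] = None,
    page: Optional[int] = None,
    page_size: Optional[int] = None,
    method: str = "GET",
    body: Optional[Mapping[str, Any]] = None,
) -> dict:
    """Issue one request and return the parsed, schema-checked envelope.

    Raises :class:`StatusError` on an HTTP error status (carrying the
    envelope's status entries), :class:`ProtocolError` when the body is not
    a valid envelope and the connection is strict.
    """
    params = dict(params or {})
    if page is not None:
        params["page"] = page
    if page_size is not None:
        params["pageSize"] = page_size
    response = request_raw(connection, call, params, method=method, body=body)
    document = response.json()
    if response.status >= 400:
        statuses = []
        if isinstance(document, dict):
            statuses = (document.get("metadata") or {}).get("status") or []
        raise StatusError(response.status, statuses)
    if connection.strict:
        violations = validate_envelope(document)
        if violations:
            raise ProtocolError(
                f"invalid response envelope from {call!r}: {violations[0]}", violations
            )
    return document


def discover(connection: Connection) -> list[dict]:
    """All call descriptors advertised by the ``/calls`` meta-endpoint.

    Walks every page, so the result covers the server's full roster.
    """
    return list(iterate_all(connection, "calls"))


class PageIterator:
    """Iterates every record of a listing call, one page at a time.

    Yields records in server order, exactly once each, issuing one request
    per page and stopping once ``currentPage`` reaches ``totalPages - 1``.
    If the reported ``totalCount`` changes between pages, the iterator
    keeps going (trusting ``totalPages`` for its loop bound) and surfaces
    the inconsistency in :attr:`warnings`.
    """

    def __init__(
        self,
        connection: Connection,
        call: str,
        params: Optional[Mapping[str, Any]] = None,
        page_size: Optional[int] = None,
        method: str = "GET",
        body: Optional[Mapping[str, Any]] = None,
    ):
        self.connection = connection
        self.call = call
        self.params = dict(params or {})
        self.page_size = page_size or connection.page_size
        self.method = method
        self.body = body
        self.warnings: list[str] = []
        self.pages_fetched = 0

    def __iter__(self) -> Iterator[Any]:
        page = 0
        first_total: Optional[int] = None
        while True:
            document = fetch_page(
                self.connection,
                self.call,
                self.params,
                page=page,
                page_size=self.page_size,
                method=self.method,
                body=self.body,
            )
            self.pages_fetched += 1
            result = document.get("result") or {}
            data = result.get("data")
            if not isinstance(data, list):
                raise ProtocolError(f"call {self.call!r} did not return a data array")
            yield from data
            pagination = (document.get("metadata") or {}).get("pagination") or {}
            total_count = pagination.get("totalCount", 0)
            total_pages = pagination.get("totalPages", 0)
            if first_total is None:
                first_total = total_count
            elif total_count != first_total:
                self.warnings.append(
                    f"totalCount changed from {first_total} to {total_count} during iteration"
                )
            current = pagination.get("currentPage", page)
            if current >= total_pages - 1 or total_pages == 0:
                return
            page = current + 1


def iterate_all(
    connection: Connection,
    call: str,
    params: Optional[Mapping[str, Any]] = None,
    page_size: Optional[int] = None,
    method: str = "GET",
    body: Optional[Mapping[str, Any]] = None,
) -> PageIterator:
    """Stream every record of a details/master-details call."""
    return PageIterator(connection, call, params, page_size, method, body)
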