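"""Zero-indexed pagination applied to every ``data`` array.

The first page is always page zero.  ``totalPages`` is the ceiling of
``totalCount / pageSize``; requesting a page at or past the end yields an
empty slice with truthful totals rather than an error, so naive page
iterators terminate cleanly.
"""

from __future__ import annotations

import math
from typing import Sequence, TypeVar

from .core_model import ALL_ZERO_PAGINATION, Pagination
from .errors import InvalidParameterError

__all__ = ["page_count", "paginate", "single_entity_pagination", "DEFAULT_PAGE_SIZE"]

T = TypeVar("T")

#: page size used when a request omits the ``pageSize`` parameter
DEFAULT_PAGE_SIZE = 1000


def page_count(total_count: int, page_size: int) -> int:
    """Number of pages needed to hold *total_count* records: ``ceil(total/size)``.

    Zero records means zero pages.
    """
    if not isinstance(page_size, int) or isinstance(page_size, bool) or page_size < 1:
        raise InvalidParameterError(f"pageSize must be a positive integer, got {page_size!r}")
    if not isinstance(total_count, int) or isinstance(total_count, bool) or total_count < 0:
        raise InvalidParameterError(f"totalCount must be non-negative, got {total_count!r}")
    return math.ceil(total_count / page_size)


def paginate(
    items: Sequence[T], page: int, page_size: int
) -> tuple[list[T], Pagination]:
    """Slice *items* to the requested zero-indexed page.

    Returns ``(slice, pagination)`` where the pagination block reports the
    truthful totals of the whole collection.  A page past the end yields an
    empty slice; negative ``page`` or non-positive ``page_size`` raise
    :class:`InvalidParameterError` (the server maps this to HTTP 400).
    """
    if not isinstance(page, int) or isinstance(page, bool) or page < 0:
        raise InvalidParameterError(f"page must be a non-negative integer, got {page!r}")
    total = len(items)
    pagination = Pagination(
        page_size=page_size,
        current_page=page,
        total_count=total,
        total_pages=page_count(total, page_size),
    )
    start = page * page_size
    return list(items[start : start + page_size]), pagination


def single_entity_pagination() -> Pagination:
    """The all-zero block that single-entity responses must carry."""
    return ALL_ZERO_PAGINATION
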