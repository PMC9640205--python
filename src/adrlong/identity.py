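"""One-way pseudonymization of push tokens.

A device's push-notification token uniquely identifies one app installation.
To link a respondent's submissions longitudinally *without* retaining a
traceable device identifier in any dataset, the server issues a random
128-bit UUID per token and keeps the (token, UUID) pairing in a private
server-side table.

The UUID is drawn from a random source, never computed from the token: a
keyed or unkeyed hash would let anyone holding candidate tokens re-identify
respondents by re-hashing, which would defeat the anonymity guarantee.
Consequently the only way back from an id to a token is the pairing table,
which is never exported (see :mod:`adrlong.ingest`).

A device that receives a fresh push token is, by design, a fresh respondent:
the pairing carries no cross-token linkage (documented limitation).
"""

from __future__ import annotations

import random
import uuid
from typing import Callable, Optional

__all__ = ["EmptyTokenError", "UnknownRespondentError", "IdentityService"]


class EmptyTokenError(ValueError):
    pass


class UnknownRespondentError(KeyError):
    pass


def _seeded_uuid_factory(seed: int) -> Callable[[], uuid.UUID]:
    """Deterministic stand-in for ``uuid.uuid4`` (tests and simulation only).

    Draws 128 random bits from a seeded PRNG and forces the version-4 /
    variant bits, so produced ids are canonically formatted like real ones.
    """
    rng = random.Random(seed)

    def factory() -> uuid.UUID:
        return uuid.UUID(int=rng.getrandbits(128), version=4)

    return factory


class IdentityService:
    """Issues stable pseudonymous respondent ids for device tokens.

    ``issue_id`` is idempotent: re-registration with a token already on file
    returns the existing id, so a reinstalled-but-same-token device never
    forks its timeline.
    """

    def __init__(self, seed: Optional[int] = None):
        self._uuid_factory: Callable[[], uuid.UUID] = (
            uuid.uuid4 if seed is None else _seeded_uuid_factory(seed)
        )
        self._id_by_token: dict[str, str] = {}
        self._token_by_id: dict[str, str] = {}

    def issue_id(self, token: str) -> str:
        """Return the respondent id paired with ``token``, issuing one if new."""
        if not token:
            raise EmptyTokenError("device token must be non-empty")
        existing = self._id_by_token.get(token)
        if existing is not None:
            return existing
        rid = str(self._uuid_factory())
        while rid in self._token_by_id:  # 2^-122 collision guard
            rid = str(self._uuid_factory())
        self._id_by_token[token] = rid
        self._token_by_id[rid] = token
        return rid

    def token_for(self, respondent_id: str) -> str:
        """Server-internal lookup used only to address push reminders.

        Never called on an analytics/export path; exports are checked to
        contain no token values.
        """
        try:
            return self._token_by_id[respondent_id]
        except KeyError:
            raise UnknownRespondentError(respondent_id) from None

    def is_issued(self, respondent_id: str) -> bool:
        return respondent_id in self._token_by_id

    def __len__(self) -> int:
        return len(self._token_by_id)
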