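"""Exception hierarchy.

Every error raised by this package derives from :class:`XrefBridgeError`, so
pipelines can catch one type at their boundary.
"""


class XrefBridgeError(Exception):
    """Base class for all errors raised by xrefbridge."""


class RegistrationConflictError(XrefBridgeError):
    """A syscode or full name is already registered with different fields."""


class UnknownDataSourceError(XrefBridgeError):
    """A syscode, full name or URN namespace is not in the registry."""


class NoUrnAvailableError(XrefBridgeError):
    """The data source has no MIRIAM namespace, so no URN can be built."""


class UrnParseError(XrefBridgeError):
    """A string is not a well-formed ``urn:miriam:<namespace>:<id>`` URN."""


class UnknownProviderError(XrefBridgeError):
    """Connection string names a provider that is not registered."""


class MapperConnectionError(XrefBridgeError):
    """A backend could not be opened from its connection parameters."""


class ClosedHandleError(XrefBridgeError):
    """Operation attempted on a mapper handle that has been closed."""


class InvalidQueryError(XrefBridgeError):
    """A free-text query is empty or otherwise unusable."""


class FlatFileParseError(XrefBridgeError):
    """Malformed tab-delimited mapping file (carries a line number)."""


class MetaboCardParseError(XrefBridgeError):
    """Malformed metabolite card file."""


class ReferentialIntegrityError(XrefBridgeError):
    """A link references an identifier absent from the DataNode table."""


class SchemaVersionError(XrefBridgeError):
    """Database file carries an unsupported schema version."""


class DatabaseOpenError(XrefBridgeError):
    """File is not a readable mapping database."""


class InvalidStackError(XrefBridgeError):
    """Stack construction with no members or invalid parameters."""


class InvalidInputError(XrefBridgeError):
    """Invalid argument to an analysis operation (empty lists, n too large)."""


class InvalidSpecError(XrefBridgeError):
    """Synthetic-world specification with impossible parameters."""
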