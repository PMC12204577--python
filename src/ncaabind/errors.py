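"""Exception hierarchy for the ncaabind pipeline.

Every stage raises a dedicated subclass of :class:`NcaabindError` so callers
can distinguish configuration problems (bad column map, unknown token) from
malformed data (unparseable peptide name, invalid SMILES).
"""


class NcaabindError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NcaabindError):
    """A required column, option or file is missing or inconsistent."""


class PeptideParseError(NcaabindError):
    """The IEDB ``Name`` field does not follow the ``SEQ + MOD(XN)`` grammar."""


class RegistryError(NcaabindError):
    """A token/SMILES registry entry is invalid or cannot be resolved."""


class TokenResolutionError(RegistryError):
    """A token id is present in neither the registry entries nor its aliases."""

    def __init__(self, token_id: str):
        self.token_id = token_id
        super().__init__(
            f"token {token_id!r} is not in the registry (entries or aliases); "
            "extend the registry with its SMILES to featurize it"
        )


class FeaturizationError(NcaabindError):
    """The descriptor engine failed on a molecule."""


class EncodingError(NcaabindError):
    """A peptide could not be mapped onto the token feature map."""
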