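"""Exception hierarchy for the triage pipeline."""


class AdmetriageError(Exception):
    """Base class for all package errors."""


class StructureParseError(AdmetriageError):
    """A SMILES string could not be parsed into a valid molecular graph."""

    def __init__(self, smiles: str, record_id: str | None = None, detail: str = ""):
        self.smiles = smiles
        self.record_id = record_id
        msg = f"cannot parse SMILES {smiles!r}"
        if record_id:
            msg += f" (record {record_id})"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class WashError(AdmetriageError):
    """Structure standardisation produced an empty or invalid molecule."""


class SchemaError(AdmetriageError):
    """An input table is missing mandatory columns or is malformed."""


class IntegrityError(AdmetriageError):
    """A dataset violates a record-level invariant (duplicate ids, bad links...)."""


class AnnotationRequiredError(AdmetriageError):
    """An active chemical entered triage without a mandatory annotation."""


class ConfigError(AdmetriageError):
    """A configuration value (threshold, rule, alert pattern) is invalid."""
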