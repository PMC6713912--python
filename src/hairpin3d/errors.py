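"""Exception hierarchy shared across the toolkit.

The CLI maps these onto stable exit codes: input problems (missing or
malformed files, bad sequences) exit 2, a missing external folding engine
exits 3, schema or model mismatches exit 4, anything else exits 1.
"""


class Hairpin3DError(Exception):
    """Base class for all toolkit errors."""


class InputError(Hairpin3DError):
    """Missing, empty, or malformed input (FASTA, Vienna, config)."""


class AlphabetError(InputError):
    """A sequence contains a character outside the legal RNA/DNA alphabet."""

    def __init__(self, record_id: str, position: int, char: str):
        self.record_id = record_id
        self.position = position  # 1-based
        self.char = char
        super().__init__(
            f"illegal character {char!r} in record {record_id!r} at position {position}"
        )


class StructureError(InputError):
    """A dot-bracket string is unbalanced, crossing, or mismatched in length."""


class SchemaError(Hairpin3DError):
    """A table or model does not match the expected 36-column feature schema."""


class ModelVersionError(SchemaError):
    """A persisted model carries an unknown or incompatible format version."""


class ExternalFolderError(Hairpin3DError):
    """The external folding engine is unavailable or emitted unparsable output."""


class FoldingBatchError(Hairpin3DError):
    """One or more records in a batch failed to fold; carries all failed ids."""

    def __init__(self, failures: dict):
        self.failures = dict(failures)
        ids = ", ".join(sorted(self.failures))
        super().__init__(f"folding failed for {len(self.failures)} record(s): {ids}")
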