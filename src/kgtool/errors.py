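"""Exception hierarchy for kgtool."""


class KGError(Exception):
    """Base class for all kgtool errors."""


class SchemaError(KGError):
    """A triple violates the knowledge-graph schema (unknown category or
    relation, illegal head/tail category pair, self-loop, malformed line)."""


class UnknownEntityError(KGError, KeyError):
    """An entity id was not found in the graph."""


class NotAGeneError(KGError):
    """An operation that requires a gene entity received another category."""


class UnknownPairError(KGError, KeyError):
    """A protein pair is absent from a similarity table.

    Callers use this to mark a gene pair *unscorable* rather than
    conflating a missing similarity with a score of zero.
    """


class UnscorablePairError(KGError):
    """A gene pair cannot be scored (no corresponding protein, or the
    similarity provider does not know the protein pair)."""


class SelfPairError(KGError):
    """A gene was scored against itself."""
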