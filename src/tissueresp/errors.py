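"""Exception hierarchy for tissueresp.

All package-specific failures derive from :class:`TissuerespError` so callers
can catch one base class at the CLI boundary.
"""


class TissuerespError(Exception):
    """Base class for all tissueresp errors."""


class MalformedIntervalError(TissuerespError):
    """An exon interval has start > end."""


class InconsistentModelError(TissuerespError):
    """Transcripts of one gene span multiple chromosomes or strands."""


class InvalidDenominatorError(TissuerespError):
    """Non-positive gene length or library size in RPKM computation."""


class UnknownGeneError(TissuerespError):
    """Counted gene identifiers missing from the gene models."""

    def __init__(self, gene_ids):
        self.gene_ids = sorted(gene_ids)
        super().__init__(
            f"{len(self.gene_ids)} gene id(s) in counts have no gene model: "
            + ", ".join(self.gene_ids[:10])
            + ("..." if len(self.gene_ids) > 10 else "")
        )


class IncompleteDesignError(TissuerespError):
    """A scoped tissue is missing its SF or GC sample."""


class FilterDomainError(TissuerespError):
    """Non-positive RPKM fed to the log-ratio; filter the table first."""


class InvalidTableError(TissuerespError):
    """Negative or inconsistent 2x2 contingency counts."""


class AnnotationParseError(TissuerespError):
    """Malformed annotation record; carries the offending line number."""

    def __init__(self, path, line_no, message):
        self.path = path
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


class SubsetViolationError(TissuerespError):
    """Study gene set is not contained in the background."""


class UndefinedDistanceError(TissuerespError):
    """Zero-variance vector under a correlation metric."""


class ConsistencyError(TissuerespError):
    """Mismatched gene sets between a tree and a data table."""


class ConfigError(TissuerespError):
    """Invalid or impossible configuration."""


class PipelineStageError(TissuerespError):
    """A pipeline stage failed; names the stage and offending records."""

    def __init__(self, stage, message):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
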