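"""Exception hierarchy for phyloflora."""


class PhylofloraError(Exception):
    """Base class for all phyloflora errors."""


class NewickError(PhylofloraError):
    """Malformed or invalid Newick input (duplicate tips, missing lengths, ...)."""


class TaxonTableError(PhylofloraError):
    """Invalid taxon table content (empty ranks, bad presence cells, ...)."""


class GraftError(PhylofloraError):
    """Grafting or dating cannot proceed (non-ultrametric backbone, bad calibration)."""


class MetricUndefinedError(PhylofloraError):
    """A metric was requested for a community on which it is undefined (e.g. singleton MPD)."""


class PipelineError(PhylofloraError):
    """A pipeline stage failed; the message names the stage."""
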