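"""Tools for resolving independent C4 photosynthesis origins in a plant
clade: carbon-isotope pathway classification, leaf gas-exchange and enzyme
phenotyping with a biochemical-subtype decision rule, low-copy ortholog
supermatrix construction, parsimony counting of origin scenarios, RPKM-based
C4 gene-copy assignment, and convergent amino-acid site scoring — plus
synthetic-data generators with known ground truth for every stage."""

from importlib import resources as _resources

__version__ = "0.1.0"

from . import convergence, io_formats, isotopes, parsimony, phenotype, supermatrix, synthetic


def packaged_data(name: str):
    """Path-like handle to a packaged data fixture (tables transcribed from
    the published study, the study-clade topology, tip states)."""
    return _resources.files("c4origins.data").joinpath(name)


__all__ = [
    "io_formats",
    "isotopes",
    "phenotype",
    "supermatrix",
    "parsimony",
    "convergence",
    "synthetic",
    "packaged_data",
]
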