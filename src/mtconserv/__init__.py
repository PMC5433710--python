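"""Conservation, selection and disease-variant recurrence analysis of
primate mitochondrial protein-coding genes."""

from .reference import (
    GeneticCode,
    GeneMap,
    PropertyTable,
    map_mtdna_position,
    translate_codon,
)
from .io import (
    CodonAlignment,
    DiseaseVariant,
    Phylogeny,
    parse_variant,
    read_codon_alignment,
    read_tree,
    read_variants,
)

__version__ = "0.1.0"


def __getattr__(name):
    # lazy high-level API to keep bare imports light
    if name in ("RunConfig", "run_conserve", "run_mapvariants",
                "run_simulate"):
        from . import pipeline

        return getattr(pipeline, name)
    if name in ("SimulationConfig", "simulate_alignment", "plant_variants"):
        from . import simulate

        return getattr(simulate, name)
    raise AttributeError(name)


__all__ = [
    "RunConfig",
    "run_conserve",
    "run_mapvariants",
    "run_simulate",
    "SimulationConfig",
    "simulate_alignment",
    "plant_variants",
    "GeneticCode",
    "GeneMap",
    "PropertyTable",
    "map_mtdna_position",
    "translate_codon",
    "CodonAlignment",
    "DiseaseVariant",
    "Phylogeny",
    "parse_variant",
    "read_codon_alignment",
    "read_tree",
    "read_variants",
    "__version__",
]
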