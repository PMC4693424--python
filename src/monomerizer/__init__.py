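"""monomerizer: infer the monomeric structure of small biological polymers.

Given a polymer's SMILES, a monomer database and the chemical reaction rules
that form inter-monomer bonds, the pipeline (1) generates each monomer's
residue family, (2) finds every residue occurrence with an index-guided
branch-and-bound subgraph isomorphism on line graphs, and (3) tiles
non-overlapping residues to cover the polymer's atoms, with light-matching
modulation and local branch-and-bound refinement when coverage is partial.
"""

from importlib import resources

from .molgraph import (
    AtomNode,
    Bond,
    BondNode,
    LineGraph,
    MolecularGraph,
    SmilesParseError,
    match_light,
    match_strict,
    parse_smiles,
    to_line_graph,
    to_smiles,
)
from .residues import (
    ReactionRule,
    Residue,
    ResidueFamily,
    Site,
    SiteInvalidError,
    apply_rule,
    build_family,
    find_sites,
    load_rules,
)
from .markov_index import FrequencyModel, MarkovIndex, build_index, learn_frequencies
from .isosearch import MatchSet, search_family, search_local, search_root
from .tiler import Tile, Tiling, greedy_tile, modulate, rank_tiles, refine_local
from .evalkit import (
    ClassificationReport,
    EvalRecord,
    GroundTruthPolymer,
    classify,
    correctness_rate,
    evaluate,
    generate_polymer,
    load_monomers,
)
from .pipeline import AnnotationConfig, AnnotationResult, Annotator

__version__ = "0.1.0"


def default_monomers():
    """The packaged 20-proteinogenic-amino-acid monomer database."""
    with resources.files(__name__).joinpath("data/monomers_amino20.json").open() as fh:
        import json

        return load_monomers(json.load(fh))


def default_rules():
    """The packaged peptide/disulfide reaction rules."""
    with resources.files(__name__).joinpath("data/rules_peptide.json").open() as fh:
        import json

        return load_rules(json.load(fh))
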