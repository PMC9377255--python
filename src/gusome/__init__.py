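"""gusome: structure-guided discovery and quantification of gut microbial
beta-glucuronidase (GUS) enzymes from metagenomic protein catalogs, with
activity-based-probe metaproteomics integration and drug-reactivation
rate association."""

from .abundance import (
    build_abundance_table,
    class_gene_abundance,
    fit_length_bias,
    normalize_abundance,
    relative_count,
)
from .align import AlignParams, PairwiseAlignment, align_pair, pairwise_identity
from .config import ClassThresholds, PipelineConfig
from .discovery import (
    assign_class,
    assign_taxonomy,
    check_conserved_residues,
    cluster_greedy,
    discover,
    screen_candidate,
    screen_catalog,
)
from .diversity import bray_curtis, distance_matrix, pcoa, permanova, shannon_index
from .kinetics import (
    associate_rates,
    fit_rate,
    fit_rates,
    specific_activity,
    wald_slope_test,
)
from .pipeline import run_pipeline
from .proteomics import (
    class_protein_abundance,
    map_peptides,
    protein_intensity,
    sequence_coverage,
    welch_t,
    wilcoxon_signed_rank,
)
from .simulate import (
    SyntheticCohort,
    TruthLabels,
    generate_catalog,
    generate_cohort,
    generate_counts,
    generate_proteome,
    generate_timecourses,
    make_cohort_metadata,
    make_representatives,
    mutate_to_identity,
    tryptic_peptides,
)
from .types import (
    AssociationResult,
    GusCall,
    GusCluster,
    ProteinRecord,
    RateEstimate,
    RepresentativeGus,
    SampleMeta,
)

__version__ = "0.1.0"


def load_default_representatives():
    """Load the bundled synthetic representative GUS set.

    The set is synthetic (deterministically generated; see
    ``make_representatives``) because the reference enzymes with solved
    structures are not redistributable here; the annotation schema is the
    same one a curated set would use.
    """
    from importlib.resources import files

    from .io import read_representatives

    data = files("gusome") / "data"
    return read_representatives(
        str(data / "representatives_synthetic.faa"),
        str(data / "representatives_synthetic.tsv"),
    )
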