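"""reosig: rank-based qualitative signatures for transcriptome classification.

Discovery and single-sample application of relative-expression-ordering (REO)
signatures — gene pairs whose within-sample ordering is stable within each
class but reversed between classes — plus the downstream statistics a
case/control transcriptome study needs: confusion/ROC evaluation, per-sample
gene-set enrichment (ssGSEA), Wilcoxon/BH differential expression, Spearman
co-expression networks and hypergeometric over-representation, and a
synthetic-cohort generator with planted, known structure for validation.
"""

__version__ = "0.1.0"

from .diffexp_network import (
    coexpression_network,
    consistent_degs,
    hypergeom_enrich,
    localize_inflammation_genes,
    wilcoxon_deg,
)
from .evaluation import (
    ClassMetrics,
    binary_auc,
    confusion_metrics,
    fold_change_summary,
    roc_auc,
    roc_points,
)
from .immune_ssgsea import (
    SsgseaScoreMatrix,
    compare_feature_by_class,
    gene_cell_correlations,
    rank_sum_test,
    ssgsea_scores,
)
from .io_preprocess import (
    ExpressionMatrix,
    GeneSetCollection,
    MatrixParseError,
    collapse_probes,
    read_gmt,
    read_labels,
    read_matrix,
    write_gmt,
    write_labels,
    write_matrix,
)
from .reo_core import (
    ReversedPair,
    ReversedPairReport,
    StablePair,
    StablePairSet,
    encode_reo,
    find_reversed_pairs,
    mine_stable_pairs,
)
from .signature import (
    UNCLASSIFIABLE,
    ClassificationResult,
    QualitativeSignature,
    SignaturePair,
    classify_matrix,
    classify_sample,
    discover_signature,
    score_sample,
)
from .synthetic_data import (
    MonotoneDistortion,
    SyntheticCohort,
    SyntheticCohortConfig,
    apply_monotone_distortion,
    generate_cohort,
)
from .pipeline_cli import run_characterize, run_discovery, run_validate

__all__ = [name for name in dir() if not name.startswith("_")]
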