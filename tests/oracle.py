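"""Brute-force reference implementation of the filter cascade.

Evaluates every criterion independently with naive set comprehensions over
the genotype matrix and annotations; kept deliberately separate from the
production cascade so the two can disagree.
"""

from tmau.variants import Zygosity


def _hom_subjects(matrix, key):
    return {
        s.id
        for s in matrix.subjects
        if matrix.zygosity(s.id, key) in (Zygosity.HOM_ALT, Zygosity.HEMI_ALT)
    }


def _carrier_subjects(matrix, key):
    return {
        s.id
        for s in matrix.subjects
        if matrix.zygosity(s.id, key)
        in (Zygosity.HET, Zygosity.HOM_ALT, Zygosity.HEMI_ALT)
    }


def _deleterious(ann, config):
    sift = None
    if ann.sift_call is not None:
        sift = ann.sift_call.value == "DELETERIOUS"
    elif ann.sift_score is not None:
        sift = ann.sift_score < config.sift_deleterious_max
    poly = None
    if ann.polyphen_call is not None:
        poly = ann.polyphen_call.value == "DAMAGING"
    elif ann.polyphen_score is not None:
        poly = ann.polyphen_score >= config.polyphen_damaging_min
    return sift is True or poly is True


def _rare(ann, config):
    if ann.maf is None:
        return True  # TREAT_AS_RARE policy
    return ann.maf < config.maf_threshold


def _gene(ann):
    return ann.gene.upper() if ann.gene else None


def brute_force_cascade(matrix, annotations, oxido_set, config):
    """Terminal and intermediate survivor sets for the default-policy cascade."""
    oxido = {g.upper() for g in oxido_set}
    known = {g.upper() for g in config.known_tma_genes}
    keys = list(matrix.variants)
    present = {k for k in keys if _hom_subjects(matrix, k)}
    pathogenic = {k for k in present if _deleterious(annotations[k], config)}
    in_oxido = {k for k in pathogenic if _gene(annotations[k]) in oxido}
    oxido_rare = {k for k in in_oxido if _rare(annotations[k], config)}
    novel = {k for k in pathogenic if _gene(annotations[k]) not in known}
    shared_any = {
        k for k in novel
        if len(_carrier_subjects(matrix, k)) >= config.min_sharing_subjects
    }
    shared_hom = {
        k for k in shared_any
        if len(_hom_subjects(matrix, k)) >= config.min_sharing_subjects
    }
    shared_rare = {k for k in shared_hom if _rare(annotations[k], config)}
    return {
        "cohort_presence": present,
        "pathogenic": pathogenic,
        "oxidoreductase_genes": in_oxido,
        "oxidoreductase_rare": oxido_rare,
        "exclude_known": novel,
        "shared_any": shared_any,
        "shared_hom": shared_hom,
        "shared_rare": shared_rare,
    }
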