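"""Score the five spatial-ecology features and apply the high-risk rule.

Plants three contrasting phenotypes, scores each map (intratumoral
strength 0-3, deserts 0/1, forests 0/1, peritumoral strength 0-3,
aggregates 0/1), and maps the scores to high-risk indicators: a patient
with two or more of {low intratumoral TILs, deserts present, forests
absent, low peritumoral TILs} falls in the high-risk group.
"""

from tilscape import (
    PhenotypeSpec,
    binarize,
    compose_map,
    high_risk_profile,
    plant_phenotype,
    resample_to_common_lattice,
    score_all,
)

for phenotype in ("cold", "desert", "mixed"):
    spec = PhenotypeSpec(phenotype=phenotype, seed=11)
    tumor_hm, lymph_hm, truth = plant_phenotype(spec)
    pair = resample_to_common_lattice(binarize(tumor_hm), binarize(lymph_hm))
    scores = score_all(compose_map(pair))
    profile = high_risk_profile(scores)
    print(f"{phenotype:>8}: strength={scores.intratumoral_strength} "
          f"deserts={scores.deserts} forests={scores.forests} "
          f"peritumoral={scores.peritumoral_strength} "
          f"aggregates={scores.aggregates}")
    print(f"          high-risk indicators {sorted(profile.indicators)} "
          f"-> count {profile.count} -> {profile.group}")
    assert scores.as_dict() == truth.as_dict()  # recovers planted truth
# the cold slide fires low-strength, desert, no-forest and low-peritumoral
# indicators at once (4 >= 2 -> high-risk); the mixed slide carries a
# forest and a busy boundary, so fewer indicators fire.
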