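"""Embed one <EHR, criteria> pair at both granularities.

The hashed-random provider stands in for a large pretrained LM: it maps
every distinct text to a reproducible unit vector, so the example runs
offline and prints the same numbers every time.
"""

from trialmatch import CriteriaSet, Document, HashedRandomProvider, build_pair

ehr = Document(
    doc_id="patient-07",
    role="ehr",
    text="76 year old with progressive memory loss MMSE 21 on donepezil",
)
criteria = CriteriaSet(
    trial_id="trial-A",
    statements=[
        Document("c0", "criterion", "age 55 to 90 years"),
        Document("c1", "criterion", "diagnosis of probable Alzheimer disease"),
        Document("c2", "criterion", "no anticoagulant therapy"),
    ],
    polarities=["inclusion", "inclusion", "exclusion"],
)

provider = HashedRandomProvider(dimension=64, seed=0)

coarse = build_pair(ehr, criteria, provider, "coarse", label=1)
fine = build_pair(ehr, criteria, provider, "fine", label=1)

print(f"coarse: EHR vector {coarse.ehr_rep.shape}, criteria vector "
      f"{coarse.criteria_rep.shape} (mean-pooled over 3 statements)")
print(f"fine:   EHR tokens {fine.ehr_rep.shape}, criteria tokens "
      f"{fine.criteria_rep.shape} (statements concatenated in order)")
print(f"first EHR vector components: {coarse.ehr_rep[:4].round(3)}")
# the shapes show one vector per document (coarse) vs one row per token
# (fine); the components are deterministic pseudo-embeddings
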