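"""Synthetic cohort simulation and the group-comparison pipeline.

Draws a table-driven cohort (three treatment groups of eight rabbits, OA vs
contralateral HT joints), then runs the gated comparison pipeline on one
measurement cell and a three-group contrast with post-hoc tests.
"""

from bonemorph import CohortSpec, compare_k, compare_two, gen_cohort

cohort = gen_cohort(CohortSpec(n_per_group={"SHAM": 7, "CONT": 8, "RIS": 8}, seed=3))
print(f"cohort: {len(cohort)} records, "
      f"{cohort.specimen.nunique()} animals, groups {sorted(set(cohort.group))}")

cell = cohort[(cohort.compartment == "MTP") & (cohort.zone == "Z4")
              & (cohort.parameter == "Cg.Th")]

# operated vs healthy joint within the untreated-OA group
oa = cell[(cell.group == "CONT") & (cell.joint == "OA")].value
ht = cell[(cell.group == "CONT") & (cell.joint == "HT")].value
res = compare_two(oa, ht)
print(f"\nCONT MTP Z4 Cg.Th, OA vs HT: {res.test} test ({res.family}), "
      f"p = {res.p_value:.4g}")
print(f"  OA {oa.mean():.1f} ± {oa.std(ddof=1):.1f} µm, "
      f"HT {ht.mean():.1f} ± {ht.std(ddof=1):.1f} µm")

# three treatment groups within the operated joint
groups = [cell[(cell.group == g) & (cell.joint == "OA")].value
          for g in ("SHAM", "CONT", "RIS")]
res3 = compare_k(groups, labels=["SHAM", "CONT", "RIS"])
print(f"\nSHAM/CONT/RIS in the OA joint: {res3.test} ({res3.family}), "
      f"omnibus p = {res3.p_value:.4g}")
print(res3.contrasts.to_string(index=False))
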