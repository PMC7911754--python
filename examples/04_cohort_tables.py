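"""Reproduce the packaged series' summary tables and test a recurrent CNV.

Recomputes the stratified percentage tables from the packaged raw counts of a
1556-case POC series, then tests the series' strongest recurrent CNV (a 16q24.3
duplication carried by 19 RPL and 0 SA cases) for SA-vs-RPL association.
"""

from poccnv import compare_counts, tables_from_counts
from poccnv.io import load_cnv_catalogue, load_table1_counts, load_table2_counts

tables = tables_from_counts(load_table1_counts(), load_table2_counts())
t1 = tables.table1.set_index("stratum")
t2 = tables.table2.set_index("stratum")
print(f"cohort n = {tables.n_cohort}, abnormal = {tables.n_abnormal} "
      f"({t1.loc['total', 'abnormal_pct']}%)")
print(f"autosomal trisomy share of abnormal : {t2.loc['total', 'autosomal_trisomy_pct']:.0f}%")
print(f"partial imbalance (CNV) share       : {t2.loc['total', 'partial_imbalance_pct']:.0f}%")

cat = load_cnv_catalogue().set_index("item")["value"]
t = compare_counts(
    int(cat["dup_16q24.3_carriers_rpl"]), int(cat["n_rpl"]),
    int(cat["dup_16q24.3_carriers_sa"]), int(cat["n_sa"]),
)
print(f"16q24.3 dup, RPL 19/1016 vs SA 0/540: {t.test_name} p = {t.p_value:.2e} "
      f"(significant at 0.05: {t.p_value < 0.05})")
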