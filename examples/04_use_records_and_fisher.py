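"""From ethnobotanical use records to binary traits and an exact 2x2 test.

Builds "any documented use" and "medicinal use" characters from a small
use-record table, scores succulence from growth-habit classes, and runs
Fisher's exact test on the succulence x medicinal-use cross-tabulation.
"""

import phylotraits as pt
from phylotraits.traits import UseRecord, UseRecordTable

records = UseRecordTable([
    UseRecord("sp_ferox", "Medicines", "Medicines"),
    UseRecord("sp_ferox", "Food", "Food"),
    UseRecord("sp_vera", "Medicines", "Medicines"),
    UseRecord("sp_arborea", "Materials", "Cordage"),
])
species = [f"sp_{n}" for n in
           ("ferox", "vera", "arborea", "gracilis", "minima", "tenuior")]
any_use, medicinal = pt.use_records_to_traits(records, species=species)
print("any_use       :", any_use.states)
print("medicinal_use :", medicinal.states)

habits = {
    "sp_ferox": "succulent_shrub", "sp_vera": "succulent_shrub",
    "sp_arborea": "branching_tree", "sp_gracilis": "barely_succulent_shrub",
    "sp_minima": "barely_succulent_shrub", "sp_tenuior": "scrambling_shrub",
}
succulence = pt.habit_to_succulence(habits, scrambler_overrides={"sp_tenuior": 1})
print("succulence    :", succulence.states)

table, excluded = pt.crosstab(succulence, medicinal)
odds, p = pt.fisher_exact(table)
print(f"\n2x2 (rows succulent 1/0, cols medicinal 1/0):\n{table}")
print(f"odds ratio = {odds:.3g}, two-sided exact p = {p:.4g}")
print("\nAt this toy size the test has no power; with a real table the p")
print("is exact (full hypergeometric enumeration, minimum-likelihood rule).")
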