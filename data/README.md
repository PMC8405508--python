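# External data

`wang2007.csv` — the published 10-subject monoexponential example dataset
(model y = 10·exp(−k·t)); columns `ID, TIME, DV`, one observation row per
subject and timepoint. It is required only by the printed-objective-value
comparison in `tests/test_acceptance.py` and is not redistributed with this
package; transcribe it from the original publication and place it here.
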