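# Cell types absent from solid tumor tissue (explicitly documented;
# the reference list is open-ended and user-extensible).
pro B-cells
Hematopoietic stem cells
Common lymphoid progenitors
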