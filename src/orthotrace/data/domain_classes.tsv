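# domain_name -> class label; families reported interchangeably for the
# same structural domain collapse to one class (editable).
RING_2	RING-class
C3HC4_2	RING-class
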