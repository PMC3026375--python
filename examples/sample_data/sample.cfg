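DB_NAME	sample
RAW_DATA	sample_data.tab
REF_MAP	sample_ref_map.tab
RELATIONSHIPS	sample_relationships.tab
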