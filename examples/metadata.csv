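sample_id,brand,batch_id,quality_class,component,sapi_percent
EXAMPLE-QA-001,EXAMPLE,EXAMPLE-QA01,quality_assured,api,99.345368
EXAMPLE-QA-002,EXAMPLE,EXAMPLE-QA01,quality_assured,api,93.0838518
EXAMPLE-QA-003,EXAMPLE,EXAMPLE-QA02,quality_assured,api,91.2259848
EXAMPLE-QA-004,EXAMPLE,EXAMPLE-QA02,quality_assured,api,95.9795367
EXAMPLE-FA-001,EXAMPLE,EXAMPLE-FA01,falsified,api,0
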