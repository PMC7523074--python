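# Canonical hexacorallian mature neuropeptides with their family ids.
# display	family_id
pQGRFamide	2
GPRGamide	1
APRGamide	1
GPRPamide	1
RPRSamide	1
pQQPPGLWamide	3
pQNPGLWamide	3
pQPGLWamide	3
pQAGAPGLWamide	3
APGLWamide	3
GPPGLWamide	3
RPPGLWamide	3
pQSPGLWamide	3
pQKSIGLWamide	3
pQFNGLWamide	3
KPPTNFGLWamide	3
LPPGPLPRPamide	4
RPRPamide	4
pQNFHLRPamide	4
pQVKLYRPamide	4
YRPamide	4
pQNLLRPamide	4
pQLLFRPamide	4
pQLFRPamide	4
pQNNLLFRPamide	4
pQRTRIRPamide	4
pQGFIRPamide	4
pQFTNWRPamide	4
pQKNPWRPamide	4
HPPLPRPamide	4
KPFFMPRPamide	4
pQITRFamide	5
pQVTRFamide	5
NPPITRIamide	5
pQSITRFamide	5
pQSVTRFamide	5
pQLVTRFamide	5
pQLTRFamide	5
pQQWTRYamide	5
QPPYLDLTPSYFHIRamide	6
phelac-LRNamide	7
phelac-YRIamide	8
phelac-YRVamide	8
phelac-YKIamide	8
phelac-FKAamide	9
pQSLRWamide	10
pQGLRWamide	10
pQGIRWamide	10
pQQQGLRWamide	10
pQGGLRWamide	10
GPPQGLRWamide	10
pQKPPGLRWamide	10
pQLLGIRWamide	10
pQGALRWamide	10
pQHGLRWamide	10
pQQKGVLRWamide	10
pQLPGIRWamide	10
pQMKGIRWamide	10
pQLGGMRWamide	10
pQAIKGLRWamide	10
pQPVASQKHGLRWamide	10
pQGLPGIRWamide	10
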