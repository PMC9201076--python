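# Sentence template bank for the synthetic note generator.
# Tab-separated: style <TAB> axis <TAB> numeral <TAB> kind <TAB> text
# axis/numeral may be '*'; kind is any|clinical|pathological.
# Placeholders: {tnm} compact pattern, {tok}/{tok_lower} bare stage token,
# {psa} a PSA value.
# --- compact frames ---------------------------------------------------------
compact	*	*	any	Staging: {tnm}.
compact	*	*	any	{tnm}.
compact	*	*	any	Final stage {tnm}.
compact	*	*	any	TNM assessment {tnm} at this visit.
compact	*	*	any	Stage assigned as {tnm}.
# --- narrative, T -----------------------------------------------------------
narrative	T	1	clinical	Digital rectal exam reveals a nonpalpable tumor.
narrative	T	1	clinical	Exam demonstrates a clinically inapparent tumor.
narrative	T	1	clinical	Incidental histologic finding of carcinoma on TURP.
narrative	T	1	clinical	Tumor identified by needle biopsy only, nonpalpable tumor on exam.
narrative	T	1	clinical	Carcinoma was an incidental finding on TURP.
narrative	T	2	clinical	Digital rectal exam demonstrates a palpable nodule confined to the prostate.
narrative	T	2	clinical	Palpable nodule on the right, tumor involves one lobe.
narrative	T	2	clinical	Disease appears limited to the prostate.
narrative	T	2	clinical	Tumor involves both lobes on imaging.
narrative	T	2	clinical	Palpable nodule noted on rectal examination.
narrative	T	2	pathological	Prostatectomy specimen shows organ confined disease.
narrative	T	2	pathological	The tumor is organ-confined with uninvolved margins.
narrative	T	2	pathological	Carcinoma confined within the prostate.
narrative	T	2	pathological	Organ confined adenocarcinoma, margins uninvolved.
narrative	T	2	pathological	Tumor confined to prostate in the prostatectomy specimen.
narrative	T	3	any	Imaging demonstrates extracapsular extension.
narrative	T	3	any	There is extraprostatic extension.
narrative	T	3	any	Seminal vesicle invasion is present.
narrative	T	3	any	Findings consistent with seminal vesicle involvement.
narrative	T	3	any	Tumor extends through the prostatic capsule.
narrative	T	3	any	Evidence of capsular penetration.
narrative	T	4	any	The mass invades the bladder neck.
narrative	T	4	any	Tumor invades the external sphincter.
narrative	T	4	any	Carcinoma invades the rectum.
narrative	T	4	any	The tumor is fixed to the pelvic wall.
narrative	T	4	any	Locally advanced disease, tumor invades adjacent structures.
# --- narrative, N -----------------------------------------------------------
narrative	N	0	any	Lymph nodes negative for tumor.
narrative	N	0	any	Dissected lymph nodes negative for carcinoma.
narrative	N	0	any	All sampled nodes free of tumor.
narrative	N	0	any	Benign lymph nodes identified in the dissection.
narrative	N	0	any	Lymph nodes negative for malignancy.
narrative	N	1	any	Pelvic lymphadenopathy consistent with nodal metastasis.
narrative	N	1	any	There is lymph node involvement.
narrative	N	1	any	Two of twelve lymph nodes positive for carcinoma.
narrative	N	1	any	Metastatic lymph nodes identified in the pelvis.
narrative	N	1	any	Tumor in regional lymph nodes.
# --- narrative, M -----------------------------------------------------------
narrative	M	0	clinical	Staging workup shows no evidence of metastatic disease.
narrative	M	0	clinical	Bone scan negative, no evidence of distant metastasis.
narrative	M	0	clinical	No sign of distant metastasis on imaging.
narrative	M	0	clinical	Negative metastatic workup.
narrative	M	0	clinical	Staging bone scan without evidence of distant metastasis.
narrative	M	1	clinical	Bone scan demonstrates osseous metastases.
narrative	M	1	clinical	Widely metastatic disease involving the spine.
narrative	M	1	clinical	Imaging reveals distant metastatic disease.
narrative	M	1	clinical	Vertebral metastases are present.
narrative	M	1	clinical	Findings compatible with metastasis to bone.
# --- ambiguous (prefix-less) phrasings --------------------------------------
ambiguous	*	*	any	{tok} disease noted at this visit.
ambiguous	*	*	any	Assessment: {tok}.
ambiguous	*	*	any	Staging documented as {tok}.
ambiguous	*	*	any	Stage recorded: {tok} at this encounter.
ambiguous	T	*	any	He has {tok_lower} prostate cancer.
ambiguous	T	*	any	Tumor stage {tok}.
ambiguous	N	*	any	Nodal status: {tok}.
ambiguous	M	*	any	Metastatic status: {tok}.
# --- negation noise (emitted only when the axis is truly benign) ------------
negation	N	*	any	No nodal metastasis identified.
negation	N	*	any	No evidence of lymph node involvement.
negation	M	*	any	No evidence of distant metastasis.
negation	M	*	any	Bone scan shows no sign of metastatic disease.
negation	T	*	any	No extracapsular extension is seen on imaging.
negation	T	*	any	No seminal vesicle invasion.
# --- historical noise (value-consistent) ------------------------------------
historical	*	*	any	History of {tok_lower} disease.
historical	*	*	any	Previously documented {tok_lower} disease.
# --- hypothetical noise ------------------------------------------------------
hypothetical	M	*	any	Will consider systemic therapy if distant metastasis develops.
hypothetical	N	*	any	If nodal metastasis is found on imaging, we would refer to oncology.
hypothetical	T	*	any	Should extracapsular extension be identified, surgery may be deferred.
# --- distractors -------------------------------------------------------------
distractor	*	*	any	PSA {psa} ng/mL.
distractor	*	*	any	Vital signs stable.
distractor	*	*	any	Continue tamsulosin 0.4 mg nightly.
distractor	*	*	any	Patient ambulating without difficulty.
distractor	*	*	any	Review of systems unremarkable.
distractor	*	*	any	Follow up in three months.
distractor	*	*	any	Denies urinary symptoms.
distractor	*	*	any	Blood pressure well controlled.
distractor	*	*	any	Colonoscopy up to date.
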