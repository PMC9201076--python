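# Prostate cancer staging lexicon (AJCC 7th edition T/N/M criteria plus
# narrative synonyms and anchor terms). Tab-separated.
# Targets: surface <TAB> axis <TAB> numeral <TAB> kind <TAB> source
# Modifiers: surface <TAB> type <TAB> direction
[targets]
# --- T1: clinically inapparent, nonpalpable tumor -------------------------
clinically inapparent tumor	T	1	clinical	AJCC
inapparent tumor	T	1	clinical	AJCC
nonpalpable tumor	T	1	clinical	AJCC
non-palpable tumor	T	1	clinical	AJCC
incidental histologic finding	T	1	clinical	AJCC
tumor identified by needle biopsy	T	1	clinical	AJCC
incidental finding on turp	T	1	clinical	expert
# --- T2: confined within the prostate -------------------------------------
organ confined	T	2		AJCC
organ-confined	T	2		AJCC
confined to the prostate	T	2		AJCC
confined within the prostate	T	2		AJCC
tumor confined to prostate	T	2		AJCC
limited to the prostate	T	2		AJCC
palpable nodule	T	2	clinical	expert
tumor involves one lobe	T	2		AJCC
tumor involves both lobes	T	2		AJCC
# --- T3: extends through the prostatic capsule ----------------------------
extracapsular extension	T	3		AJCC
extracapsular spread	T	3		expert
extraprostatic extension	T	3		AJCC
extraprostatic spread	T	3		expert
extends through the prostatic capsule	T	3		AJCC
extension beyond the capsule	T	3		expert
beyond the prostatic capsule	T	3		AJCC
capsular penetration	T	3		expert
seminal vesicle invasion	T	3		AJCC
seminal vesicle involvement	T	3		AJCC
invades the seminal vesicle	T	3		AJCC
invades the seminal vesicles	T	3		AJCC
microscopic bladder neck invasion	T	3	pathological	AJCC
ece	T	3		embedding_expansion
epe	T	3		embedding_expansion
svi	T	3		embedding_expansion
# --- T4: fixed or invades adjacent structures -----------------------------
invades the bladder neck	T	4		AJCC
invades the external sphincter	T	4		AJCC
invades the rectum	T	4		AJCC
invades the pelvic wall	T	4		AJCC
invades the levator muscles	T	4		AJCC
invades adjacent structures	T	4		AJCC
fixed to the pelvic wall	T	4		AJCC
fixed tumor	T	4		AJCC
rectal invasion	T	4		expert
bladder invasion	T	4		expert
# --- T anchors (no mapped value) ------------------------------------------
t stage	T			expert
tumor stage	T			expert
primary tumor	T			AJCC
tumor extent	T			expert
prostatic capsule	T			expert
digital rectal exam	T			expert
prostate nodule	T			expert
prostatectomy specimen	T			expert
radical prostatectomy	T			expert
gleason score	T			expert
# --- N1: regional lymph node metastasis -----------------------------------
regional lymph node metastasis	N	1		AJCC
lymph node metastasis	N	1		AJCC
lymph node metastases	N	1		AJCC
nodal metastasis	N	1		AJCC
nodal metastases	N	1		AJCC
nodal involvement	N	1		expert
lymph node involvement	N	1		expert
pelvic lymphadenopathy	N	1		expert
malignant lymphadenopathy	N	1		expert
positive lymph nodes	N	1		expert
positive pelvic nodes	N	1		expert
node positive disease	N	1		expert
nodes positive for carcinoma	N	1		expert
lymph nodes positive for carcinoma	N	1		expert
metastatic lymph nodes	N	1		expert
tumor in regional lymph nodes	N	1		AJCC
# --- N0: no regional node involvement (phrased positively) ----------------
lymph nodes negative for tumor	N	0		expert
lymph nodes negative for carcinoma	N	0		expert
lymph nodes negative for malignancy	N	0		expert
benign lymph nodes	N	0		expert
nodes free of tumor	N	0		expert
# --- N anchors -------------------------------------------------------------
lymph node	N			expert
lymph nodes	N			expert
regional nodes	N			expert
pelvic nodes	N			expert
nodal status	N			expert
n stage	N			expert
lymphadenectomy	N			expert
node dissection	N			expert
lymphadenopathy	N			expert
# --- M1: distant metastasis -------------------------------------------------
distant metastasis	M	1		AJCC
distant metastases	M	1		AJCC
distant metastatic disease	M	1		expert
bone metastasis	M	1		AJCC
bone metastases	M	1		AJCC
osseous metastasis	M	1		expert
osseous metastases	M	1		expert
skeletal metastases	M	1		expert
vertebral metastases	M	1		expert
visceral metastases	M	1		expert
metastasis to bone	M	1		expert
metastasis to the spine	M	1		expert
metastatic disease	M	1		expert
metastatic prostate cancer	M	1		expert
widely metastatic	M	1		expert
oligometastatic disease	M	1		expert
distant spread	M	1		expert
# --- M0 ---------------------------------------------------------------------
negative metastatic workup	M	0		expert
metastasis	M	1		expert
metastases	M	1		expert
# --- M anchors --------------------------------------------------------------
metastatic	M			expert
m stage	M			expert
bone scan	M			expert
distant disease	M			expert
metastatic workup	M			expert

[modifiers]
# --- negation (NegEx core) --------------------------------------------------
no	negation	forward
no evidence of	negation	forward
no sign of	negation	forward
no suspicious	negation	forward
without	negation	forward
without evidence of	negation	forward
denies	negation	forward
negative for	negation	forward
free of	negation	forward
absence of	negation	forward
absent	negation	forward
not	negation	forward
never had	negation	forward
fails to reveal	negation	forward
rules out	negation	forward
ruled out	negation	backward
was ruled out	negation	backward
is ruled out	negation	backward
not identified	negation	backward
not seen	negation	backward
not present	negation	backward
unlikely	negation	backward
# --- pseudo-negation: block the embedded trigger ---------------------------
no increase	pseudo	forward
no change	pseudo	forward
no further	pseudo	forward
not only	pseudo	forward
not necessarily	pseudo	forward
gram negative	pseudo	forward
without difficulty	pseudo	forward
# --- historical -------------------------------------------------------------
history of	historical	forward
past history of	historical	forward
known history of	historical	forward
previous	historical	forward
previously	historical	forward
prior	historical	forward
status post	historical	forward
years ago	historical	backward
# --- hypothetical -----------------------------------------------------------
if	hypothetical	forward
should	hypothetical	forward
could	hypothetical	forward
would	hypothetical	forward
in case	hypothetical	forward
in the event	hypothetical	forward
risk of	hypothetical	forward
return if	hypothetical	forward
possibility of	hypothetical	forward
watch for	hypothetical	forward
rule out	hypothetical	forward
# --- experiencer other than the patient ------------------------------------
family history of	experiencer_other	forward
father	experiencer_other	forward
mother	experiencer_other	forward
brother	experiencer_other	forward
uncle	experiencer_other	forward
son	experiencer_other	forward
family member	experiencer_other	forward
fh of	experiencer_other	forward
# --- scope termination ------------------------------------------------------
but	termination	forward
however	termination	forward
although	termination	forward
though	termination	forward
aside from	termination	forward
apart from	termination	forward
except	termination	forward
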