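# Synthetic Arabic personal-name list authored for this package
# (generator input; not drawn from any published benchmark).
محمد
أحمد
محمود
مصطفى
إبراهيم
عبدالله
عبدالرحمن
خديجة
فاطمة
عائشة
زينب
يوسف
سليمان
حمزة
خالد
سعيد
حسين
حسن
علي
عمر
صالح
طارق
ناصر
منصور
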